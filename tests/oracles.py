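"""Independent reference implementations used only by the tests.

These deliberately share no code with the package's likelihood engines:
covariances are assembled by explicit elementwise loops from the model
definition and evaluated with numpy's slogdet/inv.
"""

import numpy as np

from qtlmm.likelihood import build_design
from qtlmm.model import parameter_paths


def dense_neg2_loglik(spec, theta, data, criterion):
    """-2 log-likelihood from a from-scratch dense covariance assembly."""
    y, X, _ = build_design(spec, data)
    n, p = X.shape
    val = dict(zip(parameter_paths(spec, data), np.asarray(theta, float)))
    Sigma = np.zeros((n, n))
    for term in spec.random_terms:
        lab = term.label
        gv = data[term.grouping].astype(str).tolist()
        if term.relmat is None:
            def Aget(a, b):
                return 1.0 if a == b else 0.0
        else:
            idx = {i: k for k, i in enumerate(term.relmat.ids)}
            M = term.relmat.values

            def Aget(a, b, idx=idx, M=M):
                return M[idx[a], idx[b]]
        if term.slopes_factor is None:
            s2 = val[f"{lab}.sd"] ** 2
            for i in range(n):
                for j in range(n):
                    Sigma[i, j] += s2 * Aget(gv[i], gv[j])
        else:
            fv = data[term.slopes_factor].astype(str).tolist()
            levs = sorted(set(fv))
            sd = {l: val[f"{lab}.sd.{l}"] for l in levs}
            cor = {}
            for a in range(len(levs)):
                for b in range(a + 1, len(levs)):
                    c = val[f"{lab}.cor.{levs[a]}.{levs[b]}"]
                    cor[(levs[a], levs[b])] = cor[(levs[b], levs[a])] = c
            for i in range(n):
                for j in range(n):
                    li, lj = fv[i], fv[j]
                    k = sd[li] * sd[lj] * (1.0 if li == lj else cor[(li, lj)])
                    Sigma[i, j] += Aget(gv[i], gv[j]) * k
    if spec.residual.by_group:
        fv = data[spec.residual.factor].astype(str).tolist()
        for i in range(n):
            Sigma[i, i] += val[f"residual.sd.{fv[i]}"] ** 2
    else:
        for i in range(n):
            Sigma[i, i] += val["residual.sd"] ** 2
    Vi = np.linalg.inv(Sigma)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    r = y - X @ beta
    _, ld = np.linalg.slogdet(Sigma)
    q = r @ Vi @ r
    if criterion == "ML":
        return n * np.log(2 * np.pi) + ld + q
    _, ld2 = np.linalg.slogdet(X.T @ Vi @ X)
    return (n - p) * np.log(2 * np.pi) + ld + ld2 + q


def anova_oneway_reml(y, n_groups, reps):
    """Balanced one-way random-intercept REML via ANOVA mean squares."""
    Y = np.asarray(y, float).reshape(n_groups, reps)
    gbar = Y.mean(axis=1)
    MSA = reps * np.sum((gbar - Y.mean()) ** 2) / (n_groups - 1)
    MSE = np.sum((Y - gbar[:, None]) ** 2) / (n_groups * (reps - 1))
    return (MSA - MSE) / reps, MSE
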