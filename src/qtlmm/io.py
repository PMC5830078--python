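"""Readers and writers for the package's text formats.

Relationship matrices travel either as a square TSV (header row and first
column carry the identifiers, first header cell is ``id``) or as a sparse
triplet file (``id1<TAB>id2<TAB>value`` per nonzero cell, diagonal included).
Phenotypes are TSV with a header; genotype dosage tables are TSV with an
``id`` first column and one column per SNP, ``NA`` for missing. Model specs
are JSON documents validated against a closed schema (unknown keys are
rejected, with the JSON path in the message).
"""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd

from .covstruct import RandomTerm, ResidualSpec
from .errors import SpecError
from .model import ConstraintSet, ModelSpec
from .relmatrix import RelMatrix

READ_SYMMETRY_TOL = 1e-8


def write_relmatrix(m: RelMatrix, path, fmt: str = "square") -> None:
    if fmt == "square":
        with open(path, "w") as fh:
            fh.write("id\t" + "\t".join(m.ids) + "\n")
            for i, row in zip(m.ids, m.values):
                fh.write(i + "\t" + "\t".join(repr(float(v)) for v in row)
                         + "\n")
    elif fmt == "triplet":
        with open(path, "w") as fh:
            for a in range(m.n):
                for b in range(a, m.n):
                    v = m.values[a, b]
                    if v != 0.0:
                        fh.write(f"{m.ids[a]}\t{m.ids[b]}\t{float(v)!r}\n")
    else:
        raise ValueError(f"unknown matrix format {fmt!r}")


def read_relmatrix(path) -> RelMatrix:
    """Read a square-TSV or triplet relationship matrix (auto-detected).

    Asymmetries below 1e-8 are symmetrised; larger ones are an error.
    """
    with open(path) as fh:
        first = fh.readline()
    if first.split("\t")[0].strip() == "id":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
        ids = [str(i) for i in df.index]
        if [str(c) for c in df.columns] != ids:
            raise SpecError(f"{path}: row and column identifiers differ")
        values = df.to_numpy(dtype=float)
    else:
        ids_seen: dict[str, int] = {}
        trips = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) != 3:
                    raise SpecError(
                        f"{path}:{lineno}: expected 3 tab-separated fields")
                a, b, v = parts[0], parts[1], float(parts[2])
                for t in (a, b):
                    ids_seen.setdefault(t, len(ids_seen))
                trips.append((a, b, v))
        n = len(ids_seen)
        values = np.zeros((n, n))
        for a, b, v in trips:
            i, j = ids_seen[a], ids_seen[b]
            values[i, j] = v
            values[j, i] = v
        ids = list(ids_seen)
    asym = float(np.max(np.abs(values - values.T))) if values.size else 0.0
    if asym > READ_SYMMETRY_TOL:
        raise SpecError(f"{path}: matrix is asymmetric (max |A-A'| = {asym:g})")
    values = 0.5 * (values + values.T)
    return RelMatrix(ids, values, validate=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    return df


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_genotypes(path):
    """Genotype dosage TSV (id column + one column per SNP, NA = missing)."""
    from .scan import GenotypeTable

    df = pd.read_csv(path, sep="\t", dtype={"id": str}, na_values=["NA"])
    if df.columns[0] != "id":
        raise SpecError(f"{path}: first column must be 'id'")
    return GenotypeTable(ids=df["id"].tolist(),
                         snp_names=[str(c) for c in df.columns[1:]],
                         dosages=df.iloc[:, 1:].to_numpy(dtype=float))


def write_genotypes(g, path) -> None:
    df = pd.DataFrame(g.dosages, columns=g.snp_names)
    df.insert(0, "id", g.ids)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# model-spec JSON

_TOP_KEYS = {"response", "fixed", "random", "residual", "constraints",
             "criterion"}
_TERM_KEYS = {"grouping", "relmat", "slopes_factor", "name"}
_RES_KEYS = {"factor"}
_CON_KEYS = {"fixes", "equalities"}


def _reject_unknown(obj: dict, allowed: set, where: str) -> None:
    for k in obj:
        if k not in allowed:
            raise SpecError(f"unknown key at {where}/{k}")


def read_spec(path, relmat_cache: dict | None = None
              ) -> tuple[ModelSpec, str]:
    """Load a model spec JSON; returns (ModelSpec, criterion).

    Relationship-matrix paths inside the spec are resolved relative to the
    spec file; the string "identity" (or null) means an identity covariance.
    """
    with open(path) as fh:
        doc = json.load(fh)
    if not isinstance(doc, dict):
        raise SpecError("spec file must hold a JSON object")
    _reject_unknown(doc, _TOP_KEYS, "")
    if "response" not in doc or not isinstance(doc["response"], str):
        raise SpecError("missing or non-string key at /response")
    base = os.path.dirname(os.path.abspath(path))
    cache = relmat_cache if relmat_cache is not None else {}

    terms = []
    for i, t in enumerate(doc.get("random", [])):
        if not isinstance(t, dict):
            raise SpecError(f"/random/{i} must be an object")
        _reject_unknown(t, _TERM_KEYS, f"/random/{i}")
        if "grouping" not in t:
            raise SpecError(f"missing key at /random/{i}/grouping")
        rm = t.get("relmat")
        relmat = None
        if rm not in (None, "identity"):
            full = rm if os.path.isabs(rm) else os.path.join(base, rm)
            if full not in cache:
                cache[full] = read_relmatrix(full)
            relmat = cache[full]
        terms.append(RandomTerm(grouping=t["grouping"], relmat=relmat,
                                slopes_factor=t.get("slopes_factor"),
                                name=t.get("name")))

    res = doc.get("residual", {}) or {}
    _reject_unknown(res, _RES_KEYS, "/residual")
    residual = ResidualSpec(factor=res.get("factor"))

    con = doc.get("constraints", {}) or {}
    _reject_unknown(con, _CON_KEYS, "/constraints")
    fixes = [(str(p), float(v)) for p, v in con.get("fixes", [])]
    eqs = [(str(a), str(b)) for a, b in con.get("equalities", [])]

    criterion = doc.get("criterion", "REML")
    if criterion not in ("ML", "REML"):
        raise SpecError(f"/criterion must be 'ML' or 'REML', got {criterion!r}")

    spec = ModelSpec(response=doc["response"],
                     fixed=[str(c) for c in doc.get("fixed", [])],
                     random_terms=terms, residual=residual,
                     constraints=ConstraintSet(fixes=fixes, equalities=eqs))
    return spec, criterion
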