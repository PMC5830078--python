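"""Pedigrees and the additive genetic relationship matrix.

A pedigree is a set of individual records with parent links. From it the
additive relationship matrix A (twice the kinship matrix) is built by the
standard tabular recursion: processing parents before children,

    A[i, i] = 1 + A[father(i), mother(i)] / 2
    A[i, j] = (A[j, father(i)] + A[j, mother(i)]) / 2      (j processed first)

with missing-parent terms dropped. Monozygotic (MZ) twin groups are collapsed
to a single genome before the recursion and expanded afterwards, so twins get
A = 1 between them and identical relationships to everyone else; the resulting
matrix is then positive semi-definite but rank deficient.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import PedigreeError
from .relmatrix import RelMatrix

MISSING = "0"

_SEX_CODES = {"1": "male", "2": "female", "0": "unknown",
              "male": "male", "female": "female", "unknown": "unknown",
              "m": "male", "f": "female"}


@dataclass(frozen=True)
class PedigreeRecord:
    family_id: str
    id: str
    father_id: str | None
    mother_id: str | None
    sex: str  # "male" | "female" | "unknown"
    mz_group: str | None = None


class Pedigree:
    """Validated collection of pedigree records (row order preserved)."""

    def __init__(self, records: Iterable[PedigreeRecord]):
        self.records = list(records)
        self._index = {r.id: i for i, r in enumerate(self.records)}
        self._validate()

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def record(self, id: str) -> PedigreeRecord:
        return self.records[self._index[id]]

    def founders(self) -> list[str]:
        return [r.id for r in self.records
                if r.father_id is None and r.mother_id is None]

    def _validate(self) -> None:
        if len(self._index) != len(self.records):
            seen, dups = set(), set()
            for r in self.records:
                (dups if r.id in seen else seen).add(r.id)
            raise PedigreeError(f"duplicate individual ids: {sorted(dups)}")
        for r in self.records:
            for pid in (r.father_id, r.mother_id):
                if pid is not None and pid not in self._index:
                    raise PedigreeError(
                        f"individual {r.id!r} lists parent {pid!r} "
                        "which is not in the pedigree")
        self.topological_order()  # raises on cycles
        self._validate_mz_groups()

    def _validate_mz_groups(self) -> None:
        groups: dict[str, list[PedigreeRecord]] = {}
        for r in self.records:
            if r.mz_group is not None:
                groups.setdefault(r.mz_group, []).append(r)
        for g, members in groups.items():
            parents = {(m.father_id, m.mother_id) for m in members}
            sexes = {m.sex for m in members}
            if len(parents) > 1:
                raise PedigreeError(
                    f"MZ group {g!r}: members do not share both parents")
            if len(sexes) > 1:
                raise PedigreeError(
                    f"MZ group {g!r}: members do not share sex")

    def topological_order(self) -> list[str]:
        """Ids ordered parents-before-children (Kahn's algorithm).

        Raises PedigreeError listing one cycle if the parent graph is cyclic.
        """
        n_parents = {}
        children: dict[str, list[str]] = {r.id: [] for r in self.records}
        for r in self.records:
            ps = [p for p in (r.father_id, r.mother_id) if p is not None]
            n_parents[r.id] = len(ps)
            for p in ps:
                children[p].append(r.id)
        queue = [i for i in self.ids if n_parents[i] == 0]
        order = []
        while queue:
            i = queue.pop()
            order.append(i)
            for c in children[i]:
                n_parents[c] -= 1
                if n_parents[c] == 0:
                    queue.append(c)
        if len(order) < len(self.records):
            cycle = self._find_cycle(set(order))
            raise PedigreeError(
                "pedigree contains a parent-offspring cycle: "
                + " -> ".join(cycle))
        return order

    def _find_cycle(self, resolved: set[str]) -> list[str]:
        remaining = [i for i in self.ids if i not in resolved]
        start = remaining[0]
        path, seen = [start], {start}
        cur = start
        while True:
            r = self.record(cur)
            nxt = next(p for p in (r.father_id, r.mother_id)
                       if p is not None and p not in resolved)
            if nxt in seen:
                return path[path.index(nxt):] + [nxt]
            path.append(nxt)
            seen.add(nxt)
            cur = nxt


def read_pedigree(path) -> Pedigree:
    """Read a LINKAGE-style pedigree file.

    Whitespace/tab-delimited columns: family, id, father, mother, sex
    (1=male, 2=female, 0=unknown); "0" codes a missing parent. An optional
    7th column carries an MZ-twin group label ("0" or "NA" = none); a 6th
    column (phenotype/affection), if present, is ignored.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 5:
                raise PedigreeError(
                    f"{path}:{lineno}: expected >= 5 columns, got {len(parts)}")
            fam, iid, fid, mid, sex = parts[:5]
            mz = parts[6] if len(parts) >= 7 else MISSING
            records.append(PedigreeRecord(
                family_id=fam,
                id=iid,
                father_id=None if fid == MISSING else fid,
                mother_id=None if mid == MISSING else mid,
                sex=_SEX_CODES.get(sex.lower(), "unknown"),
                mz_group=None if mz in (MISSING, "NA", "") else mz,
            ))
    return Pedigree(records)


def write_pedigree(ped: Pedigree, path) -> None:
    """Write a pedigree in the LINKAGE layout accepted by read_pedigree."""
    sex_out = {"male": "1", "female": "2", "unknown": "0"}
    with open(path, "w") as fh:
        for r in ped:
            fh.write("\t".join([
                r.family_id, r.id,
                r.father_id or MISSING, r.mother_id or MISSING,
                sex_out[r.sex], MISSING, r.mz_group or MISSING]) + "\n")


def additive_relationship(ped: Pedigree) -> RelMatrix:
    """Additive genetic relationship matrix A over all pedigree ids.

    Members of an MZ group share one genome: A between them is the group
    diagonal value and their relationships to others coincide. Inbreeding is
    handled implicitly by the recursion (A_ii = 1 + F_i).
    """
    # Collapse MZ groups to one representative genome.
    rep: dict[str, str] = {}
    first_of_group: dict[str, str] = {}
    for r in ped:
        if r.mz_group is None:
            rep[r.id] = r.id
        else:
            rep[r.id] = first_of_group.setdefault(r.mz_group, r.id)

    # Topological order on the collapsed genome graph (MZ members share
    # parents, so collapsing cannot create a cycle).
    all_genomes = list(dict.fromkeys(rep[r.id] for r in ped))
    gparents = {g: tuple(rep[p] for p in (ped.record(g).father_id,
                                          ped.record(g).mother_id)
                         if p is not None)
                for g in all_genomes}
    n_pending = {g: len(gparents[g]) for g in all_genomes}
    gchildren: dict[str, list[str]] = {g: [] for g in all_genomes}
    for g, ps in gparents.items():
        for p in ps:
            gchildren[p].append(g)
    queue = [g for g in all_genomes if n_pending[g] == 0]
    genomes: list[str] = []
    while queue:
        g = queue.pop()
        genomes.append(g)
        for c in gchildren[g]:
            n_pending[c] -= 1
            if n_pending[c] == 0:
                queue.append(c)

    gidx = {g: k for k, g in enumerate(genomes)}
    m = len(genomes)
    Ag = np.zeros((m, m))
    for i, g in enumerate(genomes):
        r = ped.record(g)
        f = gidx[rep[r.father_id]] if r.father_id is not None else None
        mo = gidx[rep[r.mother_id]] if r.mother_id is not None else None
        Ag[i, i] = 1.0 + (0.5 * Ag[f, mo] if f is not None and mo is not None
                          else 0.0)
        if i and (f is not None or mo is not None):
            row = np.zeros(i)
            if f is not None:
                row += 0.5 * Ag[:i, f]
            if mo is not None:
                row += 0.5 * Ag[:i, mo]
            Ag[i, :i] = row
            Ag[:i, i] = row

    ids = ped.ids
    pos = np.array([gidx[rep[i]] for i in ids])
    A = Ag[np.ix_(pos, pos)]
    return RelMatrix(ids, A, validate=False)


def incidence_from_factor(values: Sequence[str], levels: Sequence[str]) -> np.ndarray:
    """0/1 incidence matrix mapping rows to factor levels.

    One row per value, columns ordered as ``levels``; exactly one 1 per row.
    """
    level_idx = {lv: j for j, lv in enumerate(levels)}
    if len(level_idx) != len(levels):
        raise ValueError("levels are not unique")
    Z = np.zeros((len(values), len(levels)))
    for i, v in enumerate(values):
        try:
            Z[i, level_idx[v]] = 1.0
        except KeyError:
            raise ValueError(f"value {v!r} not among levels {list(levels)}")
    return Z
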