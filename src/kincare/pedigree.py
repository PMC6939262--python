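"""Pedigree construction, kinship and inbreeding coefficients.

A pedigree is a directed acyclic genealogy over opaque string identifiers.
Founders (both parents missing) are assumed unrelated and non-inbred, which
fixes the base population against which all identity-by-descent probabilities
are expressed.  An individual with a single recorded parent is treated as if
the missing parent were a unique, unrelated phantom founder: the known half of
the genealogy is kept and the unknown half contributes nothing.

Two routes to the same quantity are provided: the exact recursive kinship
algorithm (memoized, robust to inbreeding loops and overlapping generations),
and a Monte Carlo gene-dropping estimator used as an independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Pedigree",
    "PedigreeError",
    "KinshipTable",
    "load_pedigree",
    "kinship",
    "inbreeding",
    "kinship_table",
    "kinship_matrix",
    "gene_drop_kinship",
]

MALE = "male"
FEMALE = "female"
UNKNOWN = "unknown"


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees or unknown identifiers."""


@dataclass
class Pedigree:
    """Validated genealogy with per-individual sire, dam, sex and cohort.

    ``sire`` / ``dam`` map each individual to its parent identifier or
    ``None`` when the parent is unrecorded.  Insertion order is irrelevant;
    a topological order is computed internally and kinship queries are
    memoized on the instance.
    """

    sire: dict[str, str | None]
    dam: dict[str, str | None]
    sex: dict[str, str]
    cohort: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._validate()
        self._depth: dict[str, int] = {}
        self._compute_depths()
        self._kin: dict[tuple[str, str], float] = {}

    # -- construction ------------------------------------------------------

    @property
    def individuals(self) -> set[str]:
        return set(self.sire)

    @property
    def founders(self) -> set[str]:
        return {i for i in self.sire if self.sire[i] is None and self.dam[i] is None}

    def parents(self, i: str) -> tuple[str | None, str | None]:
        return self.sire[i], self.dam[i]

    def add_individual(
        self,
        ident: str,
        sire: str | None,
        dam: str | None,
        sex: str = UNKNOWN,
        cohort: int | None = None,
    ) -> None:
        """Append one individual whose parents (if named) already exist."""
        if ident in self.sire:
            raise PedigreeError(f"duplicate identifier {ident!r}")
        for role, parent, bad_sex in (("sire", sire, FEMALE), ("dam", dam, MALE)):
            if parent is not None:
                if parent not in self.sire:
                    raise PedigreeError(f"{role} {parent!r} of {ident!r} is not in the pedigree")
                if self.sex[parent] == bad_sex:
                    raise PedigreeError(
                        f"{role} {parent!r} of {ident!r} is recorded as {bad_sex}"
                    )
        self.sire[ident] = sire
        self.dam[ident] = dam
        self.sex[ident] = sex
        if cohort is not None:
            self.cohort[ident] = cohort
        d = 0
        for p in (sire, dam):
            if p is not None:
                d = max(d, self._depth[p] + 1)
        self._depth[ident] = d

    def _validate(self) -> None:
        ids = list(self.sire)
        if set(ids) != set(self.dam) or set(ids) != set(self.sex):
            raise PedigreeError("sire, dam and sex maps must cover identical individuals")
        for i in ids:
            s, d = self.sire[i], self.dam[i]
            if s is not None and s not in self.sire:
                raise PedigreeError(f"sire {s!r} of {i!r} is not in the pedigree")
            if d is not None and d not in self.sire:
                raise PedigreeError(f"dam {d!r} of {i!r} is not in the pedigree")
            if s is not None and self.sex[s] == FEMALE:
                raise PedigreeError(f"sire {s!r} of {i!r} is recorded as female")
            if d is not None and self.sex[d] == MALE:
                raise PedigreeError(f"dam {d!r} of {i!r} is recorded as male")

    def _compute_depths(self) -> None:
        # Kahn's algorithm; leftover nodes imply a cycle (self-ancestry).
        children: dict[str, list[str]] = {i: [] for i in self.sire}
        indeg = {i: 0 for i in self.sire}
        for i in self.sire:
            for p in (self.sire[i], self.dam[i]):
                if p is not None:
                    children[p].append(i)
                    indeg[i] += 1
        queue = [i for i in self.sire if indeg[i] == 0]
        depth = {i: 0 for i in queue}
        order: list[str] = []
        while queue:
            n = queue.pop()
            order.append(n)
            for c in children[n]:
                depth[c] = max(depth.get(c, 0), depth[n] + 1)
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if len(order) != len(self.sire):
            cyclic = sorted(set(self.sire) - set(order))
            raise PedigreeError(f"cyclic ancestry involving {cyclic[:5]}")
        self._depth = depth
        self._order = order

    def topological_order(self) -> list[str]:
        """Individuals sorted parents-before-offspring."""
        return sorted(self.sire, key=self._depth.__getitem__)

    def _check(self, *ids: str) -> None:
        for i in ids:
            if i not in self.sire:
                raise PedigreeError(f"unknown identifier {i!r}")


def load_pedigree(path: str | Path, missing_code: str = "0") -> Pedigree:
    """Read a delimited pedigree file (columns id, sire, dam, sex[, cohort]).

    The delimiter is taken from the extension (``.tsv`` is tab, anything else
    comma).  A parent equal to ``missing_code`` (or empty) is unrecorded;
    founders are rows with both parents missing.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    required = {"id", "sire", "dam", "sex"}
    if not required.issubset(df.columns):
        raise PedigreeError(f"pedigree file must have columns {sorted(required)}")
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise PedigreeError(f"duplicate id {dup!r}")

    def clean(v: str) -> str | None:
        v = v.strip()
        return None if v in (missing_code, "") else v

    sire = {r.id: clean(r.sire) for r in df.itertuples()}
    dam = {r.id: clean(r.dam) for r in df.itertuples()}
    sex_map = {"m": MALE, "male": MALE, "f": FEMALE, "female": FEMALE}
    sex = {r.id: sex_map.get(r.sex.strip().lower(), UNKNOWN) for r in df.itertuples()}
    cohort = {}
    if "cohort" in df.columns:
        cohort = {r.id: int(r.cohort) for r in df.itertuples() if r.cohort.strip()}
    return Pedigree(sire=sire, dam=dam, sex=sex, cohort=cohort)


# -- kinship ---------------------------------------------------------------


def kinship(ped: Pedigree, i: str, j: str) -> float:
    """Coefficient of kinship k(i, j): the probability that one allele drawn
    at random from *i* and one from *j* at an autosomal locus are identical
    by descent relative to the founder generation.

    Uses the classic recursion on the younger individual (the one deeper in
    the genealogy, which cannot be an ancestor of the other):
    ``k(i, j) = (k(sire_i, j) + k(dam_i, j)) / 2`` and
    ``k(i, i) = (1 + f_i) / 2`` with ``f_i = k(sire_i, dam_i)``.
    Missing parents contribute zero.
    """
    ped._check(i, j)
    return _kin(ped, i, j)


def _kin(ped: Pedigree, i: str, j: str) -> float:
    key = (i, j) if i <= j else (j, i)
    cache = ped._kin
    val = cache.get(key)
    if val is not None:
        return val
    if i == j:
        s, d = ped.sire[i], ped.dam[i]
        f = _kin(ped, s, d) if (s is not None and d is not None) else 0.0
        val = 0.5 * (1.0 + f)
    else:
        # Recurse on the deeper individual: equal depth means neither is an
        # ancestor of the other, so either choice is valid.
        if ped._depth[i] < ped._depth[j]:
            i, j = j, i
        s, d = ped.sire[i], ped.dam[i]
        val = 0.0
        if s is not None:
            val += 0.5 * _kin(ped, s, j)
        if d is not None:
            val += 0.5 * _kin(ped, d, j)
    cache[key] = val
    return val


def inbreeding(ped: Pedigree, i: str) -> float:
    """Coefficient of inbreeding f_i = kinship of i's parents.

    Zero for founders and for any individual with an unrecorded parent
    (the phantom founder is unrelated to everyone).
    """
    ped._check(i)
    s, d = ped.sire[i], ped.dam[i]
    if s is None or d is None:
        return 0.0
    return _kin(ped, s, d)


@dataclass
class KinshipTable:
    """Batch kinship lookups: pair entries plus self-kinship diagonal."""

    entries: dict[frozenset[str], float]
    self_entries: dict[str, float]

    def k(self, i: str, j: str) -> float:
        if i == j:
            return self.self_entries[i]
        try:
            return self.entries[frozenset((i, j))]
        except KeyError:
            raise KeyError(f"no kinship entry for pair ({i!r}, {j!r})") from None

    def f(self, i: str) -> float:
        """Inbreeding coefficient recovered from the diagonal: f = 2k(i,i) - 1."""
        return 2.0 * self.self_entries[i] - 1.0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"id1": a, "id2": b, "k": v}
            for pair, v in self.entries.items()
            for a, b in [sorted(pair)]
        ]
        rows += [{"id1": i, "id2": i, "k": v} for i, v in self.self_entries.items()]
        return pd.DataFrame(rows, columns=["id1", "id2", "k"])


def kinship_table(ped: Pedigree, pairs: Iterable[tuple[str, str]]) -> KinshipTable:
    """Evaluate kinship for the requested pairs (memoized on the pedigree).

    The diagonal k(i, i) = (1 + f_i)/2 is filled for every individual that
    appears in a pair, so inbreeding coefficients come for free.
    """
    entries: dict[frozenset[str], float] = {}
    selfs: dict[str, float] = {}
    for i, j in pairs:
        ped._check(i, j)
        if i == j:
            selfs[i] = _kin(ped, i, i)
            continue
        entries[frozenset((i, j))] = _kin(ped, i, j)
        for x in (i, j):
            if x not in selfs:
                selfs[x] = _kin(ped, x, x)
    return KinshipTable(entries=entries, self_entries=selfs)


def kinship_matrix(ped: Pedigree, ids: Sequence[str] | None = None) -> pd.DataFrame:
    """Full kinship matrix over ``ids`` (default: everyone), built in one
    topological sweep; equivalent to per-pair :func:`kinship` calls."""
    order = ped.topological_order()
    idx = {v: n for n, v in enumerate(order)}
    n = len(order)
    K = np.zeros((n, n))
    for a, ind in enumerate(order):
        s, d = ped.sire[ind], ped.dam[ind]
        si = idx[s] if s is not None else None
        di = idx[d] if d is not None else None
        row = np.zeros(n)
        if si is not None:
            row += 0.5 * K[si]
        if di is not None:
            row += 0.5 * K[di]
        K[a, :] = row
        K[:, a] = row
        f = K[si, di] if (si is not None and di is not None) else 0.0
        K[a, a] = 0.5 * (1.0 + f)
    sel = list(ids) if ids is not None else order
    for i in sel:
        ped._check(i)
    pos = [idx[i] for i in sel]
    return pd.DataFrame(K[np.ix_(pos, pos)], index=sel, columns=sel)


# -- gene dropping ---------------------------------------------------------


def _drop_alleles(ped: Pedigree, n_reps: int, rng: np.random.Generator) -> tuple[np.ndarray, dict[str, int]]:
    """Simulate transmission of uniquely labelled founder alleles.

    Returns an array of shape (n_individuals, 2, n_reps) of founder-allele
    labels, and the row index of each individual.  Phantom (unrecorded)
    parents transmit fresh unique labels, i.e. behave as unrelated founders.
    """
    order = ped.topological_order()
    idx = {v: n for n, v in enumerate(order)}
    alleles = np.empty((len(order), 2, n_reps), dtype=np.int32)
    next_label = 0
    reps = np.arange(n_reps)
    for ind in order:
        row = idx[ind]
        for slot, parent in enumerate((ped.sire[ind], ped.dam[ind])):
            if parent is None:
                alleles[row, slot, :] = next_label
                next_label += 1
            else:
                pick = rng.integers(0, 2, size=n_reps)
                alleles[row, slot, :] = alleles[idx[parent], pick, reps]
    return alleles, idx


def gene_drop_kinship(
    ped: Pedigree, i: str, j: str, n_reps: int = 200_000, seed: int = 0
) -> float:
    """Monte Carlo estimate of k(i, j) by gene dropping.

    Each replicate transmits uniquely labelled founder alleles down the
    genealogy; the estimate is the frequency with which an allele drawn at
    random from *i* matches (is a copy of the same founder allele as) one
    drawn at random from *j*, averaged over the four allele pairings per
    replicate.  Standard error is at most ``0.5 / sqrt(n_reps)``.
    """
    ped._check(i, j)
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    alleles, idx = _drop_alleles(ped, n_reps, rng)
    ai, aj = alleles[idx[i]], alleles[idx[j]]
    # Average over the four ordered allele draws; for i == j the same-slot
    # draws always match, recovering P = (1 + f)/2.
    match = sum(
        (ai[a] == aj[b]).astype(np.float64) for a in (0, 1) for b in (0, 1)
    )
    return float(np.mean(match) / 4.0)
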