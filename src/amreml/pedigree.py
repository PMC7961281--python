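"""Pedigree parsing, validation and relationship-matrix algebra.

The numerator relationship matrix A holds expected additive-genetic
relationships among pedigree members; its diagonal is 1 + F where F is
the inbreeding coefficient.  The mixed-model equations only ever need
A inverse, which is sparse and is built directly from Henderson's rules;
the dense A is materialised only for moderate pedigrees.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

logger = logging.getLogger(__name__)

UNKNOWN = -1  # internal index for an unknown parent

_SEX_CODES = {"M": "M", "F": "F", "U": "U", "MALE": "M", "FEMALE": "F",
              "1": "M", "2": "F"}


class PedigreeError(ValueError):
    """Raised for structural pedigree defects (duplicates, cycles, orphans)."""


@dataclass
class PedigreeDialect:
    """File-format conventions for delimited pedigree/phenotype text."""

    delimiter: str = ","
    unknown: str = "0"
    auto_founders: bool = True


@dataclass
class Pedigree:
    """Topologically ordered pedigree.

    Attributes
    ----------
    ids : list of animal tokens in processing order (parents before progeny).
    sire, dam : integer arrays of parent positions in that order
        (``-1`` marks an unknown parent).
    generation : integer array (0 for founders unless stated in the file).
    sex : array of 'M'/'F'/'U'.
    id_index : token -> dense position mapping.
    """

    ids: list
    sire: np.ndarray
    dam: np.ndarray
    generation: np.ndarray
    sex: np.ndarray
    id_index: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.id_index:
            self.id_index = {a: i for i, a in enumerate(self.ids)}

    @property
    def n(self) -> int:
        return len(self.ids)

    def __len__(self) -> int:
        return self.n

    def to_frame(self) -> pd.DataFrame:
        unk = "0"
        return pd.DataFrame({
            "animal": self.ids,
            "sire": [self.ids[s] if s >= 0 else unk for s in self.sire],
            "dam": [self.ids[d] if d >= 0 else unk for d in self.dam],
            "generation": self.generation,
            "sex": self.sex,
        })


def _canonical_key(token):
    """Sort key giving numeric tokens numeric order, others string order."""
    s = str(token)
    try:
        return (0, float(s), s)
    except ValueError:
        return (1, 0.0, s)


def pedigree_from_frame(df: pd.DataFrame, unknown: str = "0",
                        auto_founders: bool = True) -> Pedigree:
    """Validate and topologically sort a raw pedigree table.

    Parents always precede progeny in the result.  The order is canonical
    (by ancestral depth, then id), so the same pedigree read in any row
    order yields the same ``id_index``.
    """
    df = df.copy()
    for col in ("animal", "sire", "dam"):
        if col not in df.columns:
            raise PedigreeError(f"pedigree table lacks required column {col!r}")
        df[col] = df[col].astype(str).str.strip()

    animals = df["animal"].tolist()
    seen = set()
    for a in animals:
        if a in seen:
            raise PedigreeError(f"duplicate animal id {a!r}")
        if a == unknown:
            raise PedigreeError(
                f"animal id equals the unknown-parent sentinel {unknown!r}")
        seen.add(a)

    parent_of = {}
    for a, s, d in zip(animals, df["sire"], df["dam"]):
        parent_of[a] = (s if s != unknown else None, d if d != unknown else None)

    # referenced-but-undefined parents become founders (warn) or error out
    referenced = {p for pr in parent_of.values() for p in pr if p is not None}
    orphans = sorted(referenced - seen, key=_canonical_key)
    if orphans:
        if not auto_founders:
            raise PedigreeError(
                f"parents referenced but never defined: {orphans[:10]}")
        logger.warning("inserting %d referenced-but-undefined parents as "
                       "founders: %s%s", len(orphans), orphans[:5],
                       "..." if len(orphans) > 5 else "")
        for p in orphans:
            parent_of[p] = (None, None)

    # ancestral depth by iterative DFS; detects cycles
    depth: dict = {}
    state: dict = {}  # 1 = on stack, 2 = done
    for start in parent_of:
        if start in state:
            continue
        stack = [start]
        while stack:
            node = stack[-1]
            if state.get(node) == 2:
                stack.pop()
                continue
            state[node] = 1
            ready = True
            for p in parent_of[node]:
                if p is None or state.get(p) == 2:
                    continue
                if state.get(p) == 1:
                    raise PedigreeError(
                        f"pedigree cycle detected at animal {node!r} "
                        f"(ancestor chain returns through {p!r})")
                stack.append(p)
                ready = False
            if ready:
                depth[node] = 1 + max(
                    (depth[p] for p in parent_of[node] if p is not None),
                    default=-1)
                state[node] = 2
                stack.pop()

    order = sorted(parent_of, key=lambda a: (depth[a], _canonical_key(a)))
    idx = {a: i for i, a in enumerate(order)}

    gen_map = {}
    sex_map = {}
    if "generation" in df.columns:
        gen_map = dict(zip(animals, pd.to_numeric(df["generation"]).astype(int)))
    if "sex" in df.columns:
        sex_map = {a: _SEX_CODES.get(str(x).strip().upper(), "U")
                   for a, x in zip(animals, df["sex"])}

    sire_idx = np.full(len(order), UNKNOWN, dtype=np.int64)
    dam_idx = np.full(len(order), UNKNOWN, dtype=np.int64)
    for a, i in idx.items():
        s, d = parent_of[a]
        if s is not None:
            sire_idx[i] = idx[s]
        if d is not None:
            dam_idx[i] = idx[d]

    generation = np.array([gen_map.get(a, depth[a]) for a in order], dtype=np.int64)
    sex = np.array([sex_map.get(a, "U") for a in order], dtype="U1")
    return Pedigree(ids=order, sire=sire_idx, dam=dam_idx,
                    generation=generation, sex=sex, id_index=idx)


def read_pedigree(path, dialect: PedigreeDialect | None = None) -> Pedigree:
    """Read a delimited pedigree file (header: animal,sire,dam[,generation,sex])."""
    dialect = dialect or PedigreeDialect()
    df = pd.read_csv(path, sep=dialect.delimiter, dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    return pedigree_from_frame(df, unknown=dialect.unknown,
                               auto_founders=dialect.auto_founders)


def write_pedigree(ped: Pedigree, path, delimiter: str = ",") -> None:
    ped.to_frame().to_csv(path, sep=delimiter, index=False)


def mendelian_variance_ratios(ped: Pedigree,
                              F: np.ndarray | None = None) -> np.ndarray:
    """Within-family (Mendelian-sampling) variance ratios d_i.

    d_i = 0.5 - 0.25 (F_s + F_d); an unknown parent's term is dropped,
    i.e. contributes as if F = -1 (both unknown gives d = 1).  These are
    the diagonal of D in the A = TDT' decomposition, so
    log|A| = sum(log d_i).
    """
    if F is None:
        F = inbreeding_coefficients(ped)
    Fs = np.where(ped.sire >= 0, F[np.maximum(ped.sire, 0)], -1.0)
    Fd = np.where(ped.dam >= 0, F[np.maximum(ped.dam, 0)], -1.0)
    return 0.5 - 0.25 * (Fs + Fd)


def extend_inbreeding(sire: np.ndarray, dam: np.ndarray, F: np.ndarray,
                      D: np.ndarray, start: int = 0) -> None:
    """Meuwissen–Luo recursion filling F and D in place from ``start``.

    Entries below ``start`` must already hold valid coefficients; this
    lets a growing pedigree (e.g. the breeding simulator) update
    inbreeding generation by generation without recomputing from scratch.
    """
    n = len(F)
    for i in range(start, n):
        s, d = sire[i], dam[i]
        Fs = F[s] if s >= 0 else -1.0
        Fd = F[d] if d >= 0 else -1.0
        D[i] = 0.5 - 0.25 * (Fs + Fd)
        if s < 0 or d < 0:
            F[i] = 0.0
            continue
        # traverse ancestors of i in decreasing index order
        coeff = {i: 1.0}
        heap = [-i]
        a_ii = 0.0
        while heap:
            j = -heapq.heappop(heap)
            r = coeff.pop(j, 0.0)
            if r == 0.0:
                continue
            for p in (sire[j], dam[j]):
                if p >= 0:
                    if p not in coeff:
                        heapq.heappush(heap, -int(p))
                        coeff[p] = 0.0
                    coeff[p] += 0.5 * r
            a_ii += r * r * D[j]
        F[i] = a_ii - 1.0


def inbreeding_coefficients(ped: Pedigree) -> np.ndarray:
    """Per-animal inbreeding coefficients by the Meuwissen–Luo recursion.

    Computes F_i = a_ii - 1 without forming the dense relationship
    matrix: each animal's diagonal is accumulated as sum_j L_ij^2 d_j
    over its ancestor paths.
    """
    F = np.zeros(ped.n)
    D = np.empty(ped.n)
    extend_inbreeding(ped.sire, ped.dam, F, D, start=0)
    return F


def additive_relationship(ped: Pedigree, dense_cap: int = 5000) -> np.ndarray:
    """Dense numerator relationship matrix A by the tabular method.

    a_ij = 0.5 (a_{j,s_i} + a_{j,d_i}) for j preceding i, and
    a_ii = 1 + 0.5 a_{s_i, d_i}; an unknown parent contributes 0.
    """
    n = ped.n
    if n > dense_cap:
        raise ValueError(
            f"pedigree has {n} animals; dense A capped at {dense_cap} "
            "(raise dense_cap explicitly if this is intended)")
    A = np.zeros((n, n))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[:i, s]
        if d >= 0:
            row += 0.5 * A[:i, d]
        A[:i, i] = row
        A[i, :i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return A


def a_inverse(ped: Pedigree, F: np.ndarray | None = None) -> sparse.csr_matrix:
    """Sparse inverse of A by Henderson's rules, accounting for inbreeding.

    Each animal contributes k k' / d_i at the (animal, sire, dam)
    positions, with k = (1, -0.5, -0.5) restricted to known parents and
    d_i the Mendelian-sampling variance ratio.
    """
    if F is None:
        F = inbreeding_coefficients(ped)
    d = mendelian_variance_ratios(ped, F)
    rows, cols, vals = [], [], []
    for i in range(ped.n):
        members = [(i, 1.0)]
        if ped.sire[i] >= 0:
            members.append((int(ped.sire[i]), -0.5))
        if ped.dam[i] >= 0:
            members.append((int(ped.dam[i]), -0.5))
        w = 1.0 / d[i]
        for a, ka in members:
            for b, kb in members:
                rows.append(a)
                cols.append(b)
                vals.append(ka * kb * w)
    return sparse.csr_matrix((vals, (rows, cols)), shape=(ped.n, ped.n))


def log_det_a(ped: Pedigree, F: np.ndarray | None = None) -> float:
    """log-determinant of A, from the Mendelian-sampling ratios."""
    return float(np.sum(np.log(mendelian_variance_ratios(ped, F))))
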