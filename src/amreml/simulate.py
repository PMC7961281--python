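"""Synthetic breeding-design generator.

Emulates a pedigreed truncation-selection program in poultry: a base
population of unrelated sires and dams mated 1:5, roughly 3,000 pedigreed
chicks per generation hatched in a handful of hatches, and the top males
and females on the 6-week shank-length phenotype retained as parents,
with matings between close relatives (shared parent or grandparent)
avoided.  Trait phenotypes follow the animal model

    y = generation + hatch + sex + a + m_dam + pe_dam + e

with true breeding values gene-dropped through the pedigree so that
cov(a) = A sigma2_a exactly (Mendelian-sampling variance uses parental
inbreeding).  Everything is seeded and bit-reproducible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from amreml.pedigree import Pedigree, extend_inbreeding

logger = logging.getLogger(__name__)


class SimulationError(ValueError):
    pass


def _centered(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    return arr - arr.mean() if arr.size else arr


@dataclass
class TraitArchitecture:
    """Variance components and fixed-effect profile of one trait.

    ``generation_levels`` and ``hatch_levels`` are level means; the
    generator centres them, so only their contrasts matter.  ``sex_gap``
    is the male-minus-female difference, applied symmetrically (+gap/2
    to males, -gap/2 to females) for sexually dimorphic traits.
    """

    name: str
    sigma2_a: float
    sigma2_e: float
    sigma2_m: float = 0.0
    sigma_am: float = 0.0
    sigma2_c: float = 0.0
    mean: float = 0.0
    generation_levels: tuple = ()
    hatch_levels: tuple = ()
    sex_gap: float = 0.0
    female_only: bool = False

    @property
    def sigma2_p(self) -> float:
        return (self.sigma2_a + self.sigma2_m + self.sigma2_c
                + self.sigma2_e)

    def __post_init__(self):
        for v in (self.sigma2_a, self.sigma2_m, self.sigma2_c,
                  self.sigma2_e):
            if v < 0:
                raise SimulationError(f"negative variance in trait "
                                      f"{self.name!r}")
        bound = math.sqrt(self.sigma2_a * self.sigma2_m)
        if abs(self.sigma_am) > bound + 1e-12:
            raise SimulationError(
                f"|sigma_am| exceeds sqrt(sigma2_a * sigma2_m) for "
                f"{self.name!r}")


def default_architectures() -> dict:
    """Trait architectures of the selection study this generator emulates.

    Juvenile growth traits carry direct additive + maternal permanent
    environmental variance (day-old weight additionally a maternal
    genetic term); production traits, measured on females only, are
    mostly direct-additive.  Level means come from the study's
    least-squares-mean tables; only their contrasts enter the records.
    """
    return {
        "SL6": TraitArchitecture(
            "SL6", sigma2_a=5.371, sigma2_c=1.144, sigma2_e=25.742,
            mean=77.44,
            generation_levels=(76.26, 76.00, 81.32, 77.65, 75.98),
            hatch_levels=(79.17, 76.72, 77.71, 76.17),
            sex_gap=3.06),
        "BW0": TraitArchitecture(
            "BW0", sigma2_a=1.49, sigma2_m=3.36, sigma2_c=2.32,
            sigma2_e=5.75, mean=37.78,
            generation_levels=(37.69, 37.79, 38.18, 37.66, 37.57),
            hatch_levels=(36.75, 38.01, 37.51, 38.82)),
        "BW2": TraitArchitecture(
            "BW2", sigma2_a=65.50, sigma2_c=37.86, sigma2_e=539.39,
            mean=135.47,
            generation_levels=(133.69, 118.07, 161.23, 143.45, 120.90),
            hatch_levels=(143.50, 135.46, 137.92, 125.00),
            sex_gap=3.52),
        "BW4": TraitArchitecture(
            "BW4", sigma2_a=823.9, sigma2_c=179.87, sigma2_e=3940.8,
            mean=354.88,
            generation_levels=(345.66, 313.44, 433.54, 364.09, 317.64),
            hatch_levels=(367.11, 341.89, 368.40, 342.09),
            sex_gap=14.86),
        "BW6": TraitArchitecture(
            "BW6", sigma2_a=2621.53, sigma2_c=397.41, sigma2_e=10179.7,
            mean=692.87,
            generation_levels=(668.09, 652.52, 783.38, 699.02, 661.35),
            hatch_levels=(732.05, 671.85, 694.87, 672.71),
            sex_gap=63.30),
        "ASM": TraitArchitecture(
            "ASM", sigma2_a=38.22, sigma2_c=23.23, sigma2_e=180.67,
            mean=182.90,
            generation_levels=(203.49, 187.89, 169.50, 178.78, 174.84),
            hatch_levels=(182.63, 183.83, 180.46, 184.69),
            female_only=True),
        "BW20": TraitArchitecture(
            "BW20", sigma2_a=7009.29, sigma2_e=38217.7, mean=2124.92,
            generation_levels=(1899.44, 2075.05, 2291.66, 2197.92, 2175.54),
            female_only=True),
        "BW40": TraitArchitecture(
            "BW40", sigma2_a=17923.6, sigma2_e=56607.8, mean=2815.77,
            generation_levels=(2657.53, 2732.59, 2947.46, 2807.35, 2933.95),
            female_only=True),
        "EP40": TraitArchitecture(
            "EP40", sigma2_a=29.940, sigma2_e=177.78, mean=50.90,
            generation_levels=(42.12, 53.39, 52.98, 49.47, 56.55),
            female_only=True),
        "EW40": TraitArchitecture(
            "EW40", sigma2_a=3.512, sigma2_e=11.343, mean=55.06,
            generation_levels=(54.92, 54.53, 55.31, 54.35, 56.18),
            female_only=True),
    }


@dataclass
class SimulationConfig:
    """Breeding design and trait architectures for one simulated study."""

    n_sires: int = 50
    dams_per_sire: int = 5
    progeny_per_dam: int = 12
    n_generations: int = 5
    n_hatches: int = 4
    selected_males: int = 200
    selected_females: int = 450
    selection_trait: str = "SL6"
    avoid_related: bool = True
    traits: dict = field(default_factory=default_architectures)
    # optional cross-trait correlations per effect: {(t1, t2): rho}
    r_a: dict = field(default_factory=dict)
    r_c: dict = field(default_factory=dict)
    r_e: dict = field(default_factory=dict)

    @property
    def n_dams(self) -> int:
        return self.n_sires * self.dams_per_sire

    def validate(self):
        if self.selection_trait not in self.traits:
            raise SimulationError(
                f"selection trait {self.selection_trait!r} has no "
                "architecture")
        if self.traits[self.selection_trait].female_only:
            raise SimulationError("the selection trait must be recorded on "
                                  "both sexes")
        if self.n_sires > self.selected_males:
            raise SimulationError("more mated sires than selected males")
        if self.n_dams > self.selected_females:
            raise SimulationError("more mated dams than selected females")


def _corr_lookup(table: dict, t1: str, t2: str) -> float:
    return table.get((t1, t2), table.get((t2, t1), 0.0))


def _sqrt_psd(M: np.ndarray) -> np.ndarray:
    """Symmetric square root tolerating singular (zero-variance) blocks."""
    if M.size == 0:
        return M
    w, V = np.linalg.eigh(M)
    if w.min() < -1e-8 * max(w.max(), 1.0):
        raise SimulationError("trait covariance structure is not PSD")
    return V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


class _TraitStructure:
    """Joint covariance structures over the configured traits."""

    def __init__(self, cfg: SimulationConfig):
        self.traits = list(cfg.traits)
        arch = cfg.traits
        # additive family: direct BV for every trait, maternal BV where fit
        self.u_labels = ([("a", t) for t in self.traits]
                         + [("m", t) for t in self.traits
                            if arch[t].sigma2_m > 0])
        K = len(self.u_labels)
        G = np.zeros((K, K))
        pos = {lab: i for i, lab in enumerate(self.u_labels)}
        for i, (kind_i, ti) in enumerate(self.u_labels):
            for j, (kind_j, tj) in enumerate(self.u_labels):
                if i > j:
                    continue
                if kind_i == "a" and kind_j == "a":
                    if ti == tj:
                        G[i, j] = arch[ti].sigma2_a
                    else:
                        rho = _corr_lookup(cfg.r_a, ti, tj)
                        G[i, j] = rho * math.sqrt(arch[ti].sigma2_a
                                                  * arch[tj].sigma2_a)
                elif kind_i == "m" and kind_j == "m":
                    G[i, j] = arch[ti].sigma2_m if ti == tj else 0.0
                else:
                    G[i, j] = arch[ti].sigma_am if ti == tj else 0.0
                G[j, i] = G[i, j]
        self.G = G
        self.G_sqrt = _sqrt_psd(G)
        self.pos = pos

        self.pe_traits = [t for t in self.traits if arch[t].sigma2_c > 0]
        P = np.zeros((len(self.pe_traits),) * 2)
        for i, ti in enumerate(self.pe_traits):
            for j, tj in enumerate(self.pe_traits):
                if i == j:
                    P[i, j] = arch[ti].sigma2_c
                elif i < j:
                    rho = _corr_lookup(cfg.r_c, ti, tj)
                    P[i, j] = P[j, i] = rho * math.sqrt(
                        arch[ti].sigma2_c * arch[tj].sigma2_c)
        self.P_sqrt = _sqrt_psd(P)

        R = np.zeros((len(self.traits),) * 2)
        for i, ti in enumerate(self.traits):
            for j, tj in enumerate(self.traits):
                if i == j:
                    R[i, j] = arch[ti].sigma2_e
                elif i < j:
                    rho = _corr_lookup(cfg.r_e, ti, tj)
                    R[i, j] = R[j, i] = rho * math.sqrt(
                        arch[ti].sigma2_e * arch[tj].sigma2_e)
        self.R_sqrt = _sqrt_psd(R)


class _Population:
    """Growing pedigree with gene-dropped true values."""

    def __init__(self, cfg: SimulationConfig, rng: np.random.Generator):
        cfg.validate()
        self.cfg = cfg
        self.rng = rng
        self.struct = _TraitStructure(cfg)
        self.ids: list = []
        self.sire: list = []
        self.dam: list = []
        self.generation: list = []
        self.sex: list = []
        self.u_rows: list = []
        self.pe_rows: list = []
        self._counter = 0
        self._F = np.zeros(0)
        self._D = np.zeros(0)

    def _new_id(self) -> str:
        self._counter += 1
        return f"A{self._counter:07d}"

    def _update_inbreeding(self):
        n = len(self.ids)
        start = len(self._F)
        if start == n:
            return
        F = np.zeros(n)
        D = np.empty(n)
        F[:start] = self._F
        D[:start] = self._D
        extend_inbreeding(np.asarray(self.sire), np.asarray(self.dam),
                          F, D, start=start)
        self._F, self._D = F, D

    def add_animals(self, parents, gen: int, sexes) -> np.ndarray:
        """Append animals with given (sire_idx, dam_idx) pairs; gene-drop
        their true additive values; returns their indices."""
        m = len(parents)
        first = len(self.ids)
        for (s, d), sx in zip(parents, sexes):
            self.ids.append(self._new_id())
            self.sire.append(s)
            self.dam.append(d)
            self.generation.append(gen)
            self.sex.append(sx)
        self._update_inbreeding()

        K = len(self.struct.u_labels)
        z = self.rng.standard_normal((m, K))
        phi = z @ self.struct.G_sqrt.T
        d_ratio = self._D[first:first + m]
        u = phi * np.sqrt(d_ratio)[:, None]
        for k, (s, d) in enumerate(parents):
            mid = np.zeros(K)
            if s >= 0:
                mid += 0.5 * self.u_rows[s]
            if d >= 0:
                mid += 0.5 * self.u_rows[d]
            u[k] += mid
        self.u_rows.extend(u)

        n_pe = len(self.struct.pe_traits)
        pe = (self.rng.standard_normal((m, n_pe)) @ self.struct.P_sqrt.T
              if n_pe else np.zeros((m, 0)))
        self.pe_rows.extend(pe)
        return np.arange(first, first + m)

    def pedigree(self) -> Pedigree:
        return Pedigree(ids=list(self.ids),
                        sire=np.asarray(self.sire, dtype=np.int64),
                        dam=np.asarray(self.dam, dtype=np.int64),
                        generation=np.asarray(self.generation,
                                              dtype=np.int64),
                        sex=np.asarray(self.sex, dtype="U1"))

    def truths(self) -> pd.DataFrame:
        df = pd.DataFrame({"animal": self.ids,
                           "generation": self.generation,
                           "sex": self.sex})
        U = np.asarray(self.u_rows)
        for lab, j in self.struct.pos.items():
            kind, t = lab
            df[f"{kind}_{t}"] = U[:, j]
        PE = np.asarray(self.pe_rows)
        for j, t in enumerate(self.struct.pe_traits):
            df[f"pe_{t}"] = PE[:, j]
        return df

    # ---- phenotypes -------------------------------------------------------

    def make_records(self, indices: np.ndarray, gen: int) -> pd.DataFrame:
        cfg = self.cfg
        m = len(indices)
        hatch = self.rng.integers(1, cfg.n_hatches + 1, size=m)
        sex = np.asarray(self.sex)[indices]
        U = np.asarray(self.u_rows)[indices]
        dams = np.asarray(self.dam)[indices]
        e = (self.rng.standard_normal((m, len(self.struct.traits)))
             @ self.struct.R_sqrt.T)

        out = pd.DataFrame({
            "animal": np.asarray(self.ids, dtype=object)[indices],
            "dam": [self.ids[d] if d >= 0 else "0" for d in dams],
            "generation": gen,
            "hatch": hatch,
            "sex": sex,
        })
        for j, t in enumerate(self.struct.traits):
            arch = cfg.traits[t]
            gen_dev = _centered(arch.generation_levels)
            hatch_dev = _centered(arch.hatch_levels)
            y = np.full(m, arch.mean)
            if gen_dev.size and 1 <= gen <= gen_dev.size:
                y += gen_dev[gen - 1]
            if hatch_dev.size:
                idx = np.minimum(hatch - 1, hatch_dev.size - 1)
                y += hatch_dev[idx]
            if arch.sex_gap:
                y += np.where(sex == "M", arch.sex_gap / 2,
                              -arch.sex_gap / 2)
            y += U[:, self.struct.pos[("a", t)]]
            if arch.sigma2_m > 0:
                mcol = self.struct.pos[("m", t)]
                mv = np.where(dams >= 0,
                              np.asarray(self.u_rows)[np.maximum(dams, 0),
                                                      mcol], 0.0)
                y += mv
            if arch.sigma2_c > 0:
                pcol = self.struct.pe_traits.index(t)
                pv = np.where(dams >= 0,
                              np.asarray(self.pe_rows)[np.maximum(dams, 0),
                                                       pcol], 0.0)
                y += pv
            y = y + e[:, j]
            if arch.female_only:
                y = np.where(sex == "F", y, np.nan)
            out[t] = y
        return out


def truncation_select(records: pd.DataFrame, trait: str, n_males: int,
                      n_females: int, sex_col: str = "sex"):
    """Top-ranked ids by phenotype within sex; ties broken by id.

    Returns (male_ids, female_ids) in rank order.
    """
    df = records.loc[records[trait].notna(), ["animal", sex_col, trait]]
    out = []
    for sex_code, n_keep in (("M", n_males), ("F", n_females)):
        cand = df[df[sex_col] == sex_code]
        if len(cand) < n_keep:
            raise SimulationError(
                f"only {len(cand)} {sex_code} candidates for {n_keep} "
                "selection slots")
        cand = cand.sort_values([trait, "animal"],
                                ascending=[False, True], kind="mergesort")
        out.append(cand["animal"].head(n_keep).tolist())
    return tuple(out)


def _ancestor_set(pop: _Population, idx: int) -> frozenset:
    """Parents and grandparents (for the mate-avoidance rule)."""
    anc = set()
    for p in (pop.sire[idx], pop.dam[idx]):
        if p >= 0:
            anc.add(p)
            for gp in (pop.sire[p], pop.dam[p]):
                if gp >= 0:
                    anc.add(gp)
    return frozenset(anc)


def _assign_mates(pop: _Population, sires: list, dams: list) -> list:
    """Greedy 1:dams_per_sire assignment avoiding close relatives.

    A first pass hands each sire the first compatible dams from the pool;
    a sire left short then tries to swap with an earlier sire (taking one
    of its compatible dams and giving back an incompatible one).  Only
    when no swap exists is the avoidance rule relaxed, with a warning.
    """
    cfg = pop.cfg
    anc = {i: _ancestor_set(pop, i) for i in sires + dams}

    def ok(s, d):
        return not cfg.avoid_related or not (anc[s] & anc[d])

    pool = list(dams)
    assigned = {s: [] for s in sires}
    for s in sires:
        rest = []
        for d in pool:
            if len(assigned[s]) < cfg.dams_per_sire and ok(s, d):
                assigned[s].append(d)
            else:
                rest.append(d)
        pool = rest

    relaxed = False
    for s in sires:
        while len(assigned[s]) < cfg.dams_per_sire and pool:
            d = pool.pop(0)     # d is incompatible with s (first pass)
            swapped = False
            for s2 in sires:
                if s2 == s or not ok(s2, d):
                    continue
                for k, d2 in enumerate(assigned[s2]):
                    if ok(s, d2):
                        assigned[s2][k] = d
                        assigned[s].append(d2)
                        swapped = True
                        break
                if swapped:
                    break
            if not swapped:
                assigned[s].append(d)
                relaxed = True
    if relaxed:
        logger.warning("mate-avoidance rule relaxed for some pairings")
    return [(s, assigned[s]) for s in sires]


@dataclass
class SimulatedData:
    pedigree: Pedigree
    phenotypes: pd.DataFrame
    truths: pd.DataFrame
    config: SimulationConfig
    seed: int


def simulate_dataset(cfg: SimulationConfig | None = None,
                     seed: int = 0) -> SimulatedData:
    """Run the full breeding program and return pedigree, records, truths.

    Generation 0 holds the unrelated base parents (no records); each
    later generation holds the pedigreed chicks, phenotyped and
    truncation-selected on the selection trait to produce the next
    generation's parents.
    """
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(seed)
    pop = _Population(cfg, rng)

    # base parents: unrelated founders, enough for the mating design
    founders = [( -1, -1)] * (cfg.n_sires + cfg.n_dams)
    sexes = ["M"] * cfg.n_sires + ["F"] * cfg.n_dams
    idx = pop.add_animals(founders, gen=0, sexes=sexes)
    sires = list(idx[:cfg.n_sires])
    dams = list(idx[cfg.n_sires:])

    records = []
    for gen in range(1, cfg.n_generations + 1):
        pairs = _assign_mates(pop, sires, dams)
        parents, sexes = [], []
        for s, ds in pairs:
            for d in ds:
                k = cfg.progeny_per_dam
                px = rng.integers(0, 2, size=k)
                for b in px:
                    parents.append((s, d))
                    sexes.append("M" if b else "F")
        prog = pop.add_animals(parents, gen=gen, sexes=sexes)
        recs = pop.make_records(prog, gen)
        records.append(recs)

        if gen < cfg.n_generations:
            males, females = truncation_select(
                recs, cfg.selection_trait, cfg.selected_males,
                cfg.selected_females)
            id_pos = {a: i for i, a in enumerate(pop.ids)}
            sires = [id_pos[a] for a in males[:cfg.n_sires]]
            dams = [id_pos[a] for a in females[:cfg.n_dams]]

    phenotypes = pd.concat(records, ignore_index=True)
    return SimulatedData(pedigree=pop.pedigree(), phenotypes=phenotypes,
                         truths=pop.truths(), config=cfg, seed=seed)


def simulate_pedigree(cfg: SimulationConfig | None = None, seed: int = 0):
    """Pedigree and true values of the simulated breeding program.

    Selection operates on phenotypes internally; this wrapper returns
    only the resulting pedigree and the per-animal true values.
    """
    sim = simulate_dataset(cfg, seed)
    return sim.pedigree, sim.truths


def simulate_breeding_values(ped: Pedigree, cfg: SimulationConfig,
                             seed: int = 0) -> pd.DataFrame:
    """Gene-drop true values down an existing pedigree (no selection).

    Founder (a, m) pairs are drawn from the configured covariance and
    descendants get the parental average plus Mendelian sampling scaled
    by parental inbreeding, so cov(a) = A sigma2_a exactly.
    """
    rng = np.random.default_rng(seed)
    struct = _TraitStructure(cfg)
    n = ped.n
    F = np.zeros(n)
    D = np.empty(n)
    extend_inbreeding(ped.sire, ped.dam, F, D, 0)

    K = len(struct.u_labels)
    U = np.zeros((n, K))
    z = rng.standard_normal((n, K)) @ struct.G_sqrt.T
    for i in range(n):
        u = z[i] * math.sqrt(D[i])
        s, d = ped.sire[i], ped.dam[i]
        if s >= 0:
            u = u + 0.5 * U[s]
        if d >= 0:
            u = u + 0.5 * U[d]
        U[i] = u

    df = pd.DataFrame({"animal": ped.ids, "generation": ped.generation,
                       "sex": ped.sex})
    for lab, j in struct.pos.items():
        kind, t = lab
        df[f"{kind}_{t}"] = U[:, j]
    n_pe = len(struct.pe_traits)
    if n_pe:
        PE = rng.standard_normal((n, n_pe)) @ struct.P_sqrt.T
        for j, t in enumerate(struct.pe_traits):
            df[f"pe_{t}"] = PE[:, j]
    return df


def simulate_phenotypes(ped: Pedigree, truths: pd.DataFrame,
                        cfg: SimulationConfig, seed: int = 0,
                        generations=None) -> pd.DataFrame:
    """Phenotype records for an existing pedigree given its true values.

    Records every animal by default (restrict with ``generations``);
    hatches are assigned uniformly at random, sexes come from the
    pedigree.  Female-only traits are missing for males.
    """
    rng = np.random.default_rng(seed)
    struct = _TraitStructure(cfg)
    mask = np.ones(ped.n, dtype=bool)
    if generations is not None:
        mask = np.isin(ped.generation, list(generations))
    indices = np.flatnonzero(mask)
    m = len(indices)
    tr = truths.set_index("animal")

    hatch = rng.integers(1, cfg.n_hatches + 1, size=m)
    sex = ped.sex[indices]
    dams = ped.dam[indices]
    e = rng.standard_normal((m, len(struct.traits))) @ struct.R_sqrt.T

    out = pd.DataFrame({
        "animal": [ped.ids[i] for i in indices],
        "dam": [ped.ids[d] if d >= 0 else "0" for d in dams],
        "generation": ped.generation[indices],
        "hatch": hatch,
        "sex": sex,
    })
    dam_ids = [ped.ids[d] if d >= 0 else None for d in dams]
    for j, t in enumerate(struct.traits):
        arch = cfg.traits[t]
        gen_dev = _centered(arch.generation_levels)
        hatch_dev = _centered(arch.hatch_levels)
        y = np.full(m, arch.mean)
        g = out["generation"].to_numpy()
        if gen_dev.size:
            gi = np.clip(g - 1, 0, gen_dev.size - 1)
            y += np.where(g >= 1, gen_dev[gi], 0.0)
        if hatch_dev.size:
            y += hatch_dev[np.minimum(hatch - 1, hatch_dev.size - 1)]
        if arch.sex_gap:
            y += np.where(sex == "M", arch.sex_gap / 2, -arch.sex_gap / 2)
        y = y + tr.loc[out["animal"], f"a_{t}"].to_numpy()
        if arch.sigma2_m > 0:
            mv = np.array([tr.at[d, f"m_{t}"] if d is not None else 0.0
                           for d in dam_ids])
            y = y + mv
        if arch.sigma2_c > 0:
            pv = np.array([tr.at[d, f"pe_{t}"] if d is not None else 0.0
                           for d in dam_ids])
            y = y + pv
        y = y + e[:, j]
        if arch.female_only:
            y = np.where(sex == "F", y, np.nan)
        out[t] = y
    return out


def single_trait_config(trait: str, arch: TraitArchitecture | None = None,
                        **overrides) -> SimulationConfig:
    """Convenience: a config carrying just one trait architecture."""
    base = default_architectures()
    if arch is None:
        arch = base[trait]
    cfg = SimulationConfig(traits={trait: arch}, selection_trait=trait,
                           **overrides)
    return cfg
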