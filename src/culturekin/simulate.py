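"""Factorial partial cross-fostering designs and phenotype simulation.

The generator builds populations for the cultures x environments x families
factorial in which every combination of genotype, rearing culture and
environment is created and replicated: monogamous founder pairs occupy each
culture-by-environment-by-family cell, each pair produces a brood of fixed
size per generation, and a configurable share of every brood is reciprocally
exchanged between cultures (plus within-culture control swaps that mimic the
handling without changing culture).  Phenotypes are then drawn from the
extended variance-partition model

    sigma2_P = sigma2_A + sigma2_C + sigma2_M + sigma2_CB + sigma2_ENVT
               + sigma2_R

with breeding values jointly multivariate normal with covariance
``sigma2_A * A`` and cultural values with covariance ``sigma2_C * C``, so the
covariance of the simulated trait is exact by construction (Cholesky draw)
rather than approximated by a transmission recursion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .culture import CulturalPedigree, cultural_relatedness_matrix
from .pedigree import GeneticPedigree, Individual, additive_matrix


@dataclass(frozen=True)
class DesignSpec:
    """Description of one factorial cross-fostering design.

    ``swap_fraction`` is the share of each brood exchanged with broods of a
    *different* culture; ``control_swap_fraction`` the share exchanged
    between families of the *same* culture to control for the manipulation
    itself.  ``brood_size`` must be at least two so that within-brood
    contrasts remain available for the residual variance.
    """

    n_cultures: int = 2
    n_environments: int = 1
    n_families_per_cell: int = 4
    brood_size: int = 4
    n_generations: int = 1
    swap_fraction: float = 0.0
    control_swap_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cultures < 1 or self.n_environments < 1 \
                or self.n_families_per_cell < 1:
            raise ValueError("factorial must have at least one cell")
        if self.brood_size < 2:
            raise ValueError("brood_size must be >= 2")
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        if not (0 <= self.swap_fraction <= 1
                and 0 <= self.control_swap_fraction <= 1):
            raise ValueError("swap fractions must lie in [0, 1]")
        if self.swap_fraction + self.control_swap_fraction > 1:
            raise ValueError(
                "swap_fraction + control_swap_fraction must be <= 1"
            )

    @property
    def n_offspring(self) -> int:
        return (self.n_cultures * self.n_environments
                * self.n_families_per_cell * self.brood_size
                * self.n_generations)


@dataclass(frozen=True)
class VarianceComponents:
    """Named non-negative variances of the extended model (trait units^2)."""

    sigma2_A: float = 0.0
    sigma2_C: float = 0.0
    sigma2_M: float = 0.0
    sigma2_CB: float = 0.0
    sigma2_ENVT: float = 0.0
    sigma2_R: float = 1.0

    def __post_init__(self) -> None:
        for name, v in self.as_dict().items():
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")

    def as_dict(self) -> dict[str, float]:
        return {
            "sigma2_A": self.sigma2_A, "sigma2_C": self.sigma2_C,
            "sigma2_M": self.sigma2_M, "sigma2_CB": self.sigma2_CB,
            "sigma2_ENVT": self.sigma2_ENVT, "sigma2_R": self.sigma2_R,
        }

    @property
    def total(self) -> float:
        return float(sum(self.as_dict().values()))


@dataclass
class Population:
    """A simulated (or observed) population ready for phenotyping.

    ``brood`` and ``rearing_dam`` describe the *rearing* environment (they
    follow an offspring when it is cross-fostered); the natal family is
    recoverable from the genetic pedigree.
    """

    ped: GeneticPedigree
    cped: CulturalPedigree
    brood: dict[str, str]
    rearing_dam: dict[str, str]
    environment: dict[str, str]
    manipulated: dict[str, str] = field(default_factory=dict)

    @property
    def offspring_ids(self) -> tuple[str, ...]:
        return tuple(i for i in self.ped.ids if i in self.brood)


def _cell_ids(c: int, e: int, f: int) -> tuple[str, str]:
    stem = f"c{c}e{e}f{f}"
    return f"{stem}_s", f"{stem}_d"


def make_design(spec: DesignSpec) -> Population:
    """Build the factorial population with intact natal rearing.

    Founder pairs fill every culture x environment x family cell; in
    multi-generation designs the parents of generation g+1 are drawn from
    generation-g offspring of *different* families within the same
    culture-environment cell (rotating the family index), which links
    families across the factorial while avoiding forced sib mating whenever
    more than one family per cell exists.  Deterministic given the spec.
    """
    individuals: list[Individual] = []
    cultures: dict[str, str] = {}
    brood: dict[str, str] = {}
    rearing_dam: dict[str, str] = {}
    environment: dict[str, str] = {}
    rng = np.random.default_rng(spec.seed)

    # founder generation
    pairs: dict[tuple[int, int, int], tuple[str, str]] = {}
    for c in range(spec.n_cultures):
        for e in range(spec.n_environments):
            for f in range(spec.n_families_per_cell):
                s, d = _cell_ids(c, e, f)
                individuals += [Individual(s, sex="M"),
                                Individual(d, sex="F")]
                cultures[s] = cultures[d] = f"culture{c}"
                environment[s] = environment[d] = f"env{e}"
                pairs[(c, e, f)] = (s, d)

    by_brood: dict[str, list[str]] = {}
    for g in range(1, spec.n_generations + 1):
        next_pairs: dict[tuple[int, int, int], tuple[str, str]] = {}
        for (c, e, f), (s, d) in sorted(pairs.items()):
            label = f"b_c{c}e{e}f{f}g{g}"
            kids = []
            for k in range(spec.brood_size):
                kid = f"c{c}e{e}f{f}g{g}o{k}"
                individuals.append(
                    Individual(kid, sire=s, dam=d, generation=g)
                )
                cultures[kid] = f"culture{c}"
                environment[kid] = f"env{e}"
                brood[kid] = label
                rearing_dam[kid] = d
                kids.append(kid)
            by_brood[label] = kids
        if g < spec.n_generations:
            # next parents: first offspring of family f mated with the
            # second offspring of family f+1 (same cell), random order
            for (c, e, f), (s, d) in sorted(pairs.items()):
                f2 = (f + 1) % spec.n_families_per_cell
                sire = by_brood[f"b_c{c}e{e}f{f}g{g}"][0]
                mates = by_brood[f"b_c{c}e{e}f{f2}g{g}"]
                dam = mates[min(1, len(mates) - 1)]
                if rng.random() < 0.5:
                    sire, dam = dam, sire
                next_pairs[(c, e, f)] = (sire, dam)
            pairs = next_pairs

    ped = GeneticPedigree(individuals)
    cped = CulturalPedigree(
        [Individual(r.id, r.sire, r.dam) for r in ped.members],
        {i: cultures[i] for i in ped.ids},
        genetic=ped,
    )
    return Population(
        ped=ped, cped=cped, brood=brood, rearing_dam=rearing_dam,
        environment=environment,
        manipulated={i: "none" for i in ped.ids},
    )


def random_pedigree(n: int, n_founders: int = 10,
                    seed: int | np.random.Generator | None = None
                    ) -> GeneticPedigree:
    """Random multigenerational pedigree for oracle/stress testing.

    Each non-founder draws two distinct parents from the individuals
    already created, preferentially among recent ones so pedigrees are
    several generations deep; repeated draws from overlapping ancestor
    pools create inbred loops.  Occasional unknown parents are included.
    """
    if n < n_founders + 2:
        raise ValueError("n must exceed n_founders + 1")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    records = [Individual(f"i{k}") for k in range(n_founders)]
    for k in range(n_founders, n):
        lo = max(0, k - max(4, k // 2))  # recent half (at least 4 back)
        a = int(rng.integers(lo, k))
        b = int(rng.integers(lo, k))
        while b == a:
            b = int(rng.integers(0, k))
        sire: str | None = f"i{a}"
        dam: str | None = f"i{b}"
        if rng.random() < 0.05:
            sire = None
        if rng.random() < 0.05:
            dam = None
        records.append(Individual(f"i{k}", sire=sire, dam=dam))
    return GeneticPedigree(records)


def pedigree_depth(ped: GeneticPedigree) -> int:
    """Longest parent-to-offspring chain length (founders at depth 0)."""
    sire, dam = ped.parent_arrays()
    depth = np.zeros(len(ped), dtype=int)
    for k in range(len(ped)):
        parents = [q for q in (sire[k], dam[k]) if q >= 0]
        if parents:
            depth[k] = 1 + max(depth[q] for q in parents)
    return int(depth.max())


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def apply_cross_fostering(pop: Population, spec: DesignSpec) -> Population:
    """Reciprocally exchange offspring between broods per the design.

    Per brood, ``round(swap_fraction * brood_size)`` offspring move to a
    brood of the *next* culture (a cyclic exchange over cultures within the
    same environment and family slot, so every brood both gives and
    receives the same number and brood sizes are conserved) and
    ``round(control_swap_fraction * brood_size)`` move to the next *family*
    of the same culture.  At least one natal offspring is retained whenever
    ``swap_fraction < 1`` so unmanipulated sibs remain as controls.
    Rearing links, rearing brood/dam and culture labels are updated and
    manipulation flags set.  Deterministic given ``spec.seed``.
    """
    n_swap = _round_half_away(spec.swap_fraction * spec.brood_size)
    n_ctrl = _round_half_away(spec.control_swap_fraction * spec.brood_size)
    if spec.swap_fraction < 1.0:
        n_swap = min(n_swap, spec.brood_size - 1)
    if n_swap + n_ctrl > spec.brood_size:
        n_ctrl = spec.brood_size - n_swap
    if n_swap > 0 and spec.n_cultures < 2:
        raise ValueError(
            "cross-culture swaps require n_cultures >= 2; "
            "increase n_cultures or set swap_fraction = 0"
        )
    if n_ctrl > 0 and spec.n_families_per_cell < 2:
        raise ValueError(
            "within-culture control swaps require n_families_per_cell >= 2"
        )

    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    members = {r.id: r for r in pop.ped.members}
    new_sire = {i: members[i].sire for i in pop.ped.ids}
    new_dam = {i: members[i].dam for i in pop.ped.ids}
    culture = dict(pop.cped.culture)
    brood = dict(pop.brood)
    rearing_dam = dict(pop.rearing_dam)
    manipulated = {i: "none" for i in pop.ped.ids}

    # group broods by (env, generation, family, culture) for pairing
    kids_of: dict[tuple, list[str]] = {}
    for i in pop.offspring_ids:
        key = _parse_kid(i)
        kids_of.setdefault(key[:4], []).append(i)

    def receiving_parents(c: int, e: int, f: int, g: int):
        """Current rearing couple of brood (c,e,f,g): the natal parents."""
        kid = kids_of[(c, e, f, g)][0]
        return members[kid].sire, members[kid].dam

    for (c, e, f, g), kids in sorted(kids_of.items()):
        picked = list(rng.choice(len(kids), size=n_swap + n_ctrl,
                                 replace=False)) if n_swap + n_ctrl else []
        movers = [kids[int(k)] for k in picked]
        cross, ctrl = movers[:n_swap], movers[n_swap:]
        c2 = (c + 1) % spec.n_cultures
        for kid in cross:
            s2, d2 = receiving_parents(c2, e, f, g)
            new_sire[kid], new_dam[kid] = s2, d2
            culture[kid] = f"culture{c2}"
            brood[kid] = f"b_c{c2}e{e}f{f}g{g}"
            rearing_dam[kid] = d2
            manipulated[kid] = "cross_swap"
        f2 = (f + 1) % spec.n_families_per_cell
        for kid in ctrl:
            s2, d2 = receiving_parents(c, e, f2, g)
            new_sire[kid], new_dam[kid] = s2, d2
            brood[kid] = f"b_c{c}e{e}f{f2}g{g}"
            rearing_dam[kid] = d2
            manipulated[kid] = "control_swap"

    rearing = [Individual(i, new_sire[i], new_dam[i]) for i in pop.ped.ids]
    cped = CulturalPedigree(rearing, culture, genetic=pop.ped)
    return Population(
        ped=pop.ped, cped=cped, brood=brood, rearing_dam=rearing_dam,
        environment=dict(pop.environment), manipulated=manipulated,
    )


def _parse_kid(kid: str) -> tuple[int, int, int, int, int]:
    """Invert the offspring id scheme c{c}e{e}f{f}g{g}o{k}."""
    import re

    m = re.fullmatch(r"c(\d+)e(\d+)f(\d+)g(\d+)o(\d+)", kid)
    if m is None:
        raise ValueError(f"not a generated offspring id: {kid!r}")
    c, e, f, g, k = map(int, m.groups())
    return c, e, f, g, k


def simulate_phenotypes(pop: Population, vc: VarianceComponents,
                        fixed: Mapping[str, float] | None = None,
                        mu: float = 0.0,
                        seed: int | np.random.SeedSequence | None = None,
                        env_as_fixed: bool = True,
                        maternal: str = "rearing",
                        manipulation_effect: float = 0.0) -> pd.DataFrame:
    """Draw phenotypes for all offspring of a population.

    y_i = mu + env(i) + a_i + c_i + m_dam(i) + cb_brood(i) + e_i, with
    ``a ~ MVN(0, sigma2_A * A)`` over the whole pedigree (Cholesky draw),
    ``c ~ MVN(0, sigma2_C * C)`` over the rearing pedigree, i.i.d. maternal,
    brood and (optionally random) environment effects, and i.i.d. residuals.
    ``fixed`` maps environment labels to fixed effects (default 0); with
    ``env_as_fixed=False`` environments instead receive i.i.d. random
    effects of variance ``sigma2_ENVT``.  ``maternal`` selects whether the
    maternal effect follows the rearing dam (care-giving; default) or the
    genetic dam.  Deterministic given ``seed``.
    """
    if maternal not in ("rearing", "genetic"):
        raise ValueError("maternal must be 'rearing' or 'genetic'")
    rng = np.random.default_rng(seed)
    ids = list(pop.offspring_ids)
    n = len(ids)
    members = {r.id: r for r in pop.ped.members}

    y = np.full(n, mu, dtype=float)

    if vc.sigma2_A > 0:
        A = additive_matrix(pop.ped)
        L = A.cholesky()
        a_all = np.sqrt(vc.sigma2_A) * (L @ rng.standard_normal(len(A)))
        pos = A.index
        y += np.array([a_all[pos[i]] for i in ids])
    if vc.sigma2_C > 0:
        C = cultural_relatedness_matrix(pop.cped)
        L = C.cholesky()
        c_all = np.sqrt(vc.sigma2_C) * (L @ rng.standard_normal(len(C)))
        pos = C.index
        y += np.array([c_all[pos[i]] for i in ids])

    dams = [pop.rearing_dam[i] if maternal == "rearing"
            else members[i].dam for i in ids]
    if vc.sigma2_M > 0:
        levels = sorted(set(dams))
        eff = dict(zip(levels, np.sqrt(vc.sigma2_M)
                       * rng.standard_normal(len(levels))))
        y += np.array([eff[d] for d in dams])
    if vc.sigma2_CB > 0:
        levels = sorted({pop.brood[i] for i in ids})
        eff = dict(zip(levels, np.sqrt(vc.sigma2_CB)
                       * rng.standard_normal(len(levels))))
        y += np.array([eff[pop.brood[i]] for i in ids])

    envs = [pop.environment[i] for i in ids]
    if env_as_fixed:
        fixed = dict(fixed or {})
        y += np.array([fixed.get(e, 0.0) for e in envs])
    elif vc.sigma2_ENVT > 0:
        levels = sorted(set(envs))
        eff = dict(zip(levels, np.sqrt(vc.sigma2_ENVT)
                       * rng.standard_normal(len(levels))))
        y += np.array([eff[e] for e in envs])

    if manipulation_effect != 0.0:
        y += np.array([manipulation_effect
                       if pop.manipulated.get(i, "none") != "none" else 0.0
                       for i in ids])
    if vc.sigma2_R > 0:
        y += np.sqrt(vc.sigma2_R) * rng.standard_normal(n)

    return pd.DataFrame({
        "id": ids,
        "y": y,
        "environment": envs,
        "culture": [pop.cped.culture[i] for i in ids],
        "dam": dams,
        "brood": [pop.brood[i] for i in ids],
        "manipulated": [pop.manipulated.get(i, "none") for i in ids],
    })
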