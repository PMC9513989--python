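"""Synthetic longitudinal cohorts with full ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: a rooted clone tree whose per-stage cellular prevalences obey the
pigeonhole sum rule, bulk read counts for paired peripheral-blood (PB) and
bone-marrow (BM) samples at each disease stage, single cells amplified with
MDA-style allelic dropout and false-positive errors, and clonal CNV
segments whose aberrant-cell fraction changes across stages.

Two views of clonal abundance are carried side by side.  ``clone_fractions``
holds *exclusive* fractions — the fraction of cells whose most-derived clone
is c — which sum with the normal-cell remainder to 1 and drive single-cell
clone sampling.  ``prevalence`` holds clade sums (the cancer cell fraction
of each clone's mutations) and is the matrix on which the sum rule
``phi(parent) >= sum phi(children)`` holds by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import CnvSegment, SampleMeta, VariantRecord

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_tree_and_prevalences",
    "simulate_bulk_counts",
    "simulate_single_cells",
    "simulate_cnv",
    "DEFAULT_PARENTS",
    "DEFAULT_PREVALENCE",
]

#: Default scripted five-clone architecture: a founder clone, an early clone
#: that vanishes by AML, a rising clone that comes to dominate, a
#: MDS-specific clone, and an AML-emergent clone.  Values are clade
#: prevalences (CCFs) per stage.
DEFAULT_PARENTS = (-1, 0, 0, 2, 2)
DEFAULT_PREVALENCE = (
    (0.50, 0.85, 0.90),  # founder
    (0.40, 0.10, 0.00),  # early clone, fades
    (0.05, 0.60, 0.85),  # rising clone
    (0.00, 0.45, 0.00),  # MDS-specific
    (0.00, 0.05, 0.80),  # AML-emergent
)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults emulate the longitudinal design the pipeline targets: three
    disease stages with paired PB/BM whole-genome samples at ~45x coverage,
    ~1,500 somatic mutations split over five clones with stage-specific
    rise-and-fall dynamics, 96 targeted single cells per stage with MDA
    dropout, and clonal CNVs whose cellular fraction grows with progression.
    """

    n_clones: int = 5
    n_mutations_per_clone: int = 300
    stages: tuple[str, ...] = ("FA", "MDS", "AML")
    compartments: tuple[str, ...] = ("BM", "PB")
    depth_mean: float = 45.0
    purity: float = 1.0
    #: s.d. of the per-variant expected-VAF jitter between paired PB and BM
    pb_bm_noise: float = 0.15
    n_cells: int = 96
    ado_rate: float = 0.2
    fp_rate: float = 0.005
    cell_depth_mean: float = 50.0
    #: scripted tree as parent index per clone (-1 = root); None -> random tree
    parents: tuple[int, ...] | None = DEFAULT_PARENTS
    #: scripted clade-prevalence matrix (clones x stages); None -> random draw
    prevalence: tuple[tuple[float, ...], ...] | None = DEFAULT_PREVALENCE
    #: (chrom, start, end, copy_number, per-stage aberrant fraction)
    cnv_specs: tuple[tuple[str, int, int, int, tuple[float, ...]], ...] = (
        ("chr1", 150_000_000, 210_000_000, 3, (0.0, 0.30, 0.70)),
        ("chr17", 5_000_000, 25_000_000, 1, (0.0, 0.20, 0.60)),
        ("chr8", 0, 145_000_000, 3, (0.0, 0.00, 0.50)),
    )
    cnv_ratio_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pb_bm_noise", "ado_rate", "fp_rate"):
            v = getattr(self, name)
            if name != "pb_bm_noise" and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.purity <= 1.0:
            raise ValueError(f"purity must be in (0, 1], got {self.purity}")
        if self.depth_mean <= 0 or self.cell_depth_mean <= 0:
            raise ValueError("depths must be > 0")
        if self.n_clones < 1:
            raise ValueError("n_clones must be >= 1")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")

    def sample_id(self, stage: str, compartment: str) -> str:
        return f"{stage}_{compartment}"

    def sample_manifest(self) -> list[SampleMeta]:
        return [
            SampleMeta(
                sample_id=self.sample_id(st, cp),
                timepoint_label=str(i),
                stage=st,
                compartment=cp,
                purity=self.purity,
            )
            for i, st in enumerate(self.stages)
            for cp in self.compartments
        ]


@dataclass
class GroundTruth:
    """Complete truth of a simulated cohort.

    Attributes
    ----------
    parents : per-clone parent index, -1 for the root (normal cells).
    clone_of_mutation : clone index per mutation (aligned with mutation ids).
    mutation_ids : stable variant ids, ``chrN:pos:ref:alt``.
    prevalence : clones x stages clade prevalences (CCFs); sum rule holds.
    clone_fractions : clones x stages exclusive fractions; column sums <= 1.
    """

    parents: np.ndarray
    clone_of_mutation: np.ndarray
    mutation_ids: list[str]
    prevalence: pd.DataFrame
    clone_fractions: pd.DataFrame
    stages: tuple[str, ...] = ("FA", "MDS", "AML")
    cell_labels: dict[str, np.ndarray] = field(default_factory=dict)

    def clade(self, clone: int) -> list[int]:
        """Clone indices in the clade rooted at ``clone`` (inclusive)."""
        children: dict[int, list[int]] = {}
        for c, p in enumerate(self.parents):
            children.setdefault(int(p), []).append(c)
        out, stack = [], [clone]
        while stack:
            c = stack.pop()
            out.append(c)
            stack.extend(children.get(c, []))
        return sorted(out)

    def genotype(self, clone: int) -> np.ndarray:
        """Binary mutation carrier profile of a clone: union of the root path."""
        carried = np.zeros(len(self.mutation_ids), dtype=bool)
        c = clone
        while c != -1:
            carried |= self.clone_of_mutation == c
            c = int(self.parents[c])
        return carried


def _exclusive_from_clades(parents: np.ndarray, prev: np.ndarray) -> np.ndarray:
    """Exclusive clone fractions from clade prevalences: phi_c - sum children."""
    excl = prev.copy()
    for c, p in enumerate(parents):
        if p >= 0:
            excl[p] -= prev[c]
    return excl


def _clades_from_exclusive(parents: np.ndarray, excl: np.ndarray) -> np.ndarray:
    prev = excl.copy()
    # children have higher indices than parents by construction
    for c in range(len(parents) - 1, -1, -1):
        p = parents[c]
        if p >= 0:
            prev[p] += prev[c]
    return prev


def simulate_tree_and_prevalences(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> GroundTruth:
    """Draw (or adopt the scripted) clone tree and per-stage prevalences.

    Scripted trajectories are validated against the sum rule; an infeasible
    script (a stage where children outgrow their parent) raises naming the
    stage.  Random draws use a stick-breaking allocation of cell mass down
    the tree, so the sum rule holds by construction.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    K, S = config.n_clones, len(config.stages)

    if config.parents is not None and len(config.parents) == K:
        parents = np.asarray(config.parents, dtype=int)
    else:
        parents = np.array([-1] + [int(rng.integers(0, c)) for c in range(1, K)], dtype=int)
    for c, p in enumerate(parents):
        if p >= c:
            raise ValueError("parents must be topologically ordered (parent index < child index)")

    if config.prevalence is not None and np.shape(config.prevalence) == (K, S):
        prev = np.asarray(config.prevalence, dtype=float)
        _validate_sum_rule(parents, prev, config.stages)
    else:
        # stick-breaking: each node passes a random share of its mass to its
        # children; root mass (total tumor content of the sample) ~ U(0.5, 1)
        prev = np.zeros((K, S))
        children: dict[int, list[int]] = {}
        for c, p in enumerate(parents):
            children.setdefault(int(p), []).append(c)
        for s in range(S):
            budget = {-1: float(rng.uniform(0.5, 1.0))}
            for c in range(K):
                p = int(parents[c])
                sibs = children[p]
                if c == sibs[0]:
                    # split the parent's budget among children + retained mass
                    w = rng.dirichlet(np.ones(len(sibs) + 1))
                    for sib, frac in zip(sibs, w[:-1]):
                        budget[sib] = budget[p] * float(frac)
                prev[c, s] = budget[c]
        _validate_sum_rule(parents, prev, config.stages)

    excl = _exclusive_from_clades(parents, prev)
    n_mut = K * config.n_mutations_per_clone
    clone_of_mut = np.repeat(np.arange(K), config.n_mutations_per_clone)
    mutation_ids = _mutation_ids(n_mut, rng)

    return GroundTruth(
        parents=parents,
        clone_of_mutation=clone_of_mut,
        mutation_ids=mutation_ids,
        prevalence=pd.DataFrame(prev, columns=list(config.stages)),
        clone_fractions=pd.DataFrame(excl, columns=list(config.stages)),
        stages=config.stages,
    )


def _validate_sum_rule(parents: np.ndarray, prev: np.ndarray, stages: Sequence[str]) -> None:
    eps = 1e-9
    excl = _exclusive_from_clades(parents, prev)
    for s, stage in enumerate(stages):
        if np.any(excl[:, s] < -eps):
            bad = int(np.argmin(excl[:, s]))
            raise ValueError(
                f"infeasible trajectory at stage {stage!r}: children of clone "
                f"{bad} exceed its prevalence ({prev[bad, s]:.3f})"
            )
        roots = prev[parents == -1, s].sum()
        if roots > 1 + eps:
            raise ValueError(
                f"infeasible trajectory at stage {stage!r}: top-level clones sum to {roots:.3f} > 1"
            )
        if np.any(prev[:, s] < -eps) or np.any(prev[:, s] > 1 + eps):
            raise ValueError(f"prevalences must lie in [0, 1] at stage {stage!r}")


_BASES = np.array(list("ACGT"))


def _mutation_ids(n: int, rng: np.random.Generator) -> list[str]:
    """Deterministic synthetic SNV ids spread over autosomes outside the default CNVs."""
    chroms = [f"chr{c}" for c in (2, 4, 5, 6, 9, 10, 11, 12)]
    ids = []
    positions = rng.choice(90_000_000, size=n, replace=False) + 1_000_000
    for i in range(n):
        ref = _BASES[rng.integers(0, 4)]
        alt = rng.permutation([b for b in "ACGT" if b != ref])[0]
        ids.append(f"{chroms[i % len(chroms)]}:{int(positions[i])}:{ref}:{alt}")
    return ids


def expected_vaf(
    prevalence: float, purity: float, copy_number: int = 2, multiplicity: int = 1
) -> float:
    """Expected VAF of a mutation with clade prevalence (CCF) ``prevalence``.

    vaf = purity * multiplicity * CCF / (purity * CN + (1 - purity) * 2).
    """
    return purity * multiplicity * prevalence / (purity * copy_number + (1 - purity) * 2)


def simulate_bulk_counts(
    truth: GroundTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[VariantRecord]:
    """Simulate bulk read counts for every stage x compartment sample.

    Per mutation, the BM expected VAF follows the purity/copy-number model
    with CCF equal to its clone's clade prevalence; the PB expected VAF adds
    a per-variant Gaussian jitter (s.d. ``pb_bm_noise``), truncated to
    [0, 1].  Depths are Poisson(depth_mean); alt counts binomial.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    n_mut = len(truth.mutation_ids)
    S = len(config.stages)
    ccf = truth.prevalence.to_numpy()  # clades x stages

    mut_ccf = ccf[truth.clone_of_mutation, :]  # mutations x stages
    bm_vaf = expected_vaf(mut_ccf, config.purity)
    jitter = rng.normal(0.0, config.pb_bm_noise, size=(n_mut, S)) if config.pb_bm_noise > 0 else 0.0
    pb_vaf = np.clip(bm_vaf + jitter, 0.0, 1.0)

    exp_by_comp = {"BM": bm_vaf, "PB": pb_vaf}
    records: list[VariantRecord] = []
    depths = {
        (cp, s): rng.poisson(config.depth_mean, size=n_mut)
        for s in range(S)
        for cp in config.compartments
    }
    alts = {
        (cp, s): rng.binomial(depths[(cp, s)], exp_by_comp.get(cp, bm_vaf)[:, s])
        for s in range(S)
        for cp in config.compartments
    }
    for i, vid in enumerate(truth.mutation_ids):
        chrom, pos, ref, alt = vid.split(":")
        obs = {}
        for s, stage in enumerate(config.stages):
            for cp in config.compartments:
                d = int(depths[(cp, s)][i])
                obs[config.sample_id(stage, cp)] = (int(alts[(cp, s)][i]), d)
        records.append(
            VariantRecord(chrom=chrom, pos=int(pos), ref=ref, alt=alt, observations=obs)
        )
    return records


def simulate_single_cells(
    truth: GroundTruth,
    config: SimulationConfig,
    stage: str,
    loci: Sequence[str] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Simulate an MDA-amplified targeted single-cell experiment at one stage.

    Cells draw a clone proportionally to the stage's exclusive clone
    fractions, with a normal-cell category taking the remaining mass.  For a
    locus the cell's clone carries, allelic dropout (probability
    ``ado_rate``) makes the site look wildtype; otherwise the mutant allele
    fraction is Beta(20, 20) around 0.5 (MDA imbalance).  Non-carried loci
    accumulate false-positive alt reads at ``fp_rate``.

    Returns (alt, total) cells x loci DataFrames and the true clone label
    per cell (-1 = normal).
    """
    if stage not in config.stages:
        raise ValueError(f"unknown stage {stage!r}; config has {config.stages}")
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    s = config.stages.index(stage)
    if loci is None:
        loci = truth.mutation_ids
    loci = list(loci)
    locus_idx = {vid: i for i, vid in enumerate(truth.mutation_ids)}
    missing = [l for l in loci if l not in locus_idx]
    if missing:
        raise ValueError(f"loci not in truth: {missing[:3]}")

    excl = truth.clone_fractions.to_numpy()[:, s]
    normal = max(0.0, 1.0 - excl.sum())
    probs = np.append(excl, normal)
    probs = probs / probs.sum()
    n = config.n_cells
    clone_draw = rng.choice(len(probs), size=n, p=probs)
    labels = np.where(clone_draw == len(excl), -1, clone_draw)

    genotypes = {c: truth.genotype(c) for c in range(config.n_clones)}
    zero = np.zeros(len(truth.mutation_ids), dtype=bool)

    cell_ids = [f"{stage}_cell{j:03d}" for j in range(n)]
    alt = np.zeros((n, len(loci)), dtype=int)
    tot = np.zeros((n, len(loci)), dtype=int)
    for j in range(n):
        g = genotypes.get(int(labels[j]), zero)
        for k, vid in enumerate(loci):
            d = int(rng.poisson(config.cell_depth_mean))
            tot[j, k] = d
            if d == 0:
                continue
            if g[locus_idx[vid]]:
                if rng.random() < config.ado_rate:
                    alt[j, k] = rng.binomial(d, config.fp_rate)
                else:
                    frac = rng.beta(20, 20)
                    alt[j, k] = rng.binomial(d, frac)
            else:
                alt[j, k] = rng.binomial(d, config.fp_rate)
    alt_df = pd.DataFrame(alt, index=cell_ids, columns=loci)
    tot_df = pd.DataFrame(tot, index=cell_ids, columns=loci)
    return alt_df, tot_df, labels


def simulate_cnv(
    truth: GroundTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[CnvSegment]:
    """Simulate per-stage depth ratios for the configured CNV segments.

    R = (2 (1 - f) + CN f) / 2 plus Gaussian noise; f is the configured
    aberrant-cell fraction at the stage.
    """
    rng = np.random.default_rng(config.seed + 3) if rng is None else rng
    segs: list[CnvSegment] = []
    for chrom, start, end, cn, fracs in config.cnv_specs:
        if cn == 2:
            raise ValueError(f"CNV spec {chrom}:{start}-{end} has CN=2 (not an aberration)")
        if len(fracs) != len(config.stages):
            raise ValueError("cnv spec needs one fraction per stage")
        for s, stage in enumerate(config.stages):
            f = float(fracs[s])
            ratio = (2 * (1 - f) + cn * f) / 2 + float(rng.normal(0, config.cnv_ratio_sd))
            segs.append(
                CnvSegment(
                    chrom=chrom,
                    start=start,
                    end=end,
                    depth_ratio=max(ratio, 1e-6),
                    copy_number=cn,
                    patient_id="SIM01",
                    stage=stage,
                )
            )
    return segs


def calibrate_pb_noise(
    truth: GroundTruth,
    config: SimulationConfig,
    stage: str,
    target_r: float = 0.7,
    n_draws: int = 200_000,
    rng: np.random.Generator | None = None,
) -> float:
    """Jitter s.d. giving a target PB-BM correlation of expected VAFs.

    Bisects ``pb_bm_noise`` so that the population correlation between BM
    expected VAFs (drawn uniformly over the truth's mutations at ``stage``)
    and the jittered, [0, 1]-truncated PB expected VAFs equals ``target_r``.
    Truncation at 0 matters for low-VAF clones, so the solution is found
    numerically rather than by the untruncated closed form
    sigma = tau sqrt(1/r^2 - 1).
    """
    if not 0 < target_r < 1:
        raise ValueError("target_r must be in (0, 1)")
    rng = np.random.default_rng(config.seed + 4) if rng is None else rng
    s = config.stages.index(stage)
    ccf = truth.prevalence.to_numpy()[truth.clone_of_mutation, s]
    bm = expected_vaf(ccf, config.purity)
    idx = rng.integers(0, len(bm), size=n_draws)
    x = bm[idx]
    noise = rng.standard_normal(n_draws)

    def corr_at(sigma: float) -> float:
        y = np.clip(x + sigma * noise, 0.0, 1.0)
        return float(np.corrcoef(x, y)[0, 1])

    lo, hi = 1e-6, 2.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if corr_at(mid) > target_r:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_cohort(config: SimulationConfig):
    """Convenience wrapper: truth, bulk records, per-stage single cells, CNVs.

    All randomness flows from ``config.seed`` through one spawned generator
    per component, so each component is reproducible in isolation.
    """
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    truth = simulate_tree_and_prevalences(config, np.random.default_rng(seeds[0]))
    records = simulate_bulk_counts(truth, config, np.random.default_rng(seeds[1]))
    sc_rng = np.random.default_rng(seeds[2])
    single_cells = {}
    for stage in config.stages:
        alt, tot, labels = simulate_single_cells(truth, config, stage, rng=sc_rng)
        single_cells[stage] = (alt, tot, labels)
        truth.cell_labels[stage] = labels
    cnvs = simulate_cnv(truth, config, np.random.default_rng(seeds[3]))
    return truth, records, single_cells, cnvs
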