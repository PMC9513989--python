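"""Single-cell targeted genotyping and clone assignment.

Calls per-cell genotypes at targeted loci with the coverage/VAF rule used
for MDA-amplified cells (callable at depth >= 5, mutant when VAF > 5%),
assigns cells to clone profiles with a two-parameter dropout/false-positive
likelihood, and flags loci whose mutated fraction differs between
compartments (stem cells vs whole PB/BM).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "call_genotype",
    "CellGenotypeMatrix",
    "mutated_cell_fraction",
    "CloneAssigner",
    "compartment_comparison",
]

MUTANT, WILDTYPE, MISSING = 1, 0, -9


def call_genotype(alt_depth: int, total_depth: int, depth_min: int = 5, vaf_min: float = 0.05) -> int:
    """Genotype call for one cell x locus observation.

    ``missing`` below ``depth_min`` total reads; otherwise ``mutant`` when
    VAF is strictly above ``vaf_min`` and ``wildtype`` otherwise (a VAF of
    exactly ``vaf_min`` is wildtype; a depth of exactly ``depth_min`` is
    callable).
    """
    if alt_depth < 0 or total_depth < 0:
        raise ValueError(f"depths must be non-negative, got ({alt_depth}, {total_depth})")
    if alt_depth > total_depth:
        raise ValueError(f"alt_depth {alt_depth} exceeds total_depth {total_depth}")
    if total_depth < depth_min:
        return MISSING
    return MUTANT if alt_depth / total_depth > vaf_min else WILDTYPE


@dataclass
class CellGenotypeMatrix:
    """Cells x loci genotype calls with their read-count support.

    ``calls`` holds 1 (mutant), 0 (wildtype) and -9 (missing).
    """

    calls: pd.DataFrame
    alt: pd.DataFrame
    total: pd.DataFrame
    depth_min: int = 5
    vaf_min: float = 0.05

    @classmethod
    def from_counts(
        cls, alt: pd.DataFrame, total: pd.DataFrame, depth_min: int = 5, vaf_min: float = 0.05
    ) -> "CellGenotypeMatrix":
        if not alt.index.equals(total.index) or not alt.columns.equals(total.columns):
            raise ValueError("alt and total must share index and columns")
        a, d = alt.to_numpy(), total.to_numpy()
        if (a < 0).any() or (d < 0).any() or (a > d).any():
            raise ValueError("require 0 <= alt <= total elementwise")
        calls = np.full(a.shape, WILDTYPE, dtype=int)
        with np.errstate(invalid="ignore", divide="ignore"):
            vaf = np.divide(a, d, out=np.zeros_like(a, dtype=float), where=d > 0)
        calls[vaf > vaf_min] = MUTANT
        calls[d < depth_min] = MISSING
        return cls(
            calls=pd.DataFrame(calls, index=alt.index, columns=alt.columns),
            alt=alt,
            total=total,
            depth_min=depth_min,
            vaf_min=vaf_min,
        )


def mutated_cell_fraction(matrix: CellGenotypeMatrix, locus: str) -> tuple[float, int, int]:
    """Mutant / (mutant + wildtype) at one locus, missing calls excluded.

    Returns ``(fraction, n_mutant, n_called)``; the fraction is NaN when
    every call at the locus is missing.
    """
    if locus not in matrix.calls.columns:
        raise KeyError(f"locus {locus!r} not in matrix")
    col = matrix.calls[locus]
    n_mut = int((col == MUTANT).sum())
    n_called = int((col != MISSING).sum())
    frac = n_mut / n_called if n_called else float("nan")
    return frac, n_mut, n_called


class CloneAssigner(BaseEstimator):
    """Dropout-aware maximum-likelihood assignment of cells to clone profiles.

    The miscall model has two parameters: allelic dropout ``ado_rate``
    (a truly mutant site called wildtype) and ``fp_rate`` (a wildtype site
    called mutant).  Per cell and clone g the log-likelihood sums over
    non-missing loci:

        P(mutant | g=1) = 1 - ado_rate     P(wildtype | g=1) = ado_rate
        P(mutant | g=0) = fp_rate          P(wildtype | g=0) = 1 - fp_rate

    The prior over clones (plus an all-wildtype normal profile) is uniform.
    A cell is unassigned when the gap between its two best log-likelihoods
    is below ``gap_min`` nats, or when it has no informative locus.

    Attributes
    ----------
    profiles_ : clones x loci binary DataFrame including the ``normal`` row.
    """

    def __init__(self, ado_rate: float = 0.2, fp_rate: float = 0.005, gap_min: float = 2.0,
                 add_normal: bool = True):
        self.ado_rate = ado_rate
        self.fp_rate = fp_rate
        self.gap_min = gap_min
        self.add_normal = add_normal

    def fit(self, profiles: pd.DataFrame, y=None):
        """Store clone genotype profiles (clones x loci, entries 0/1).

        Profiles should be nested along ancestry (an ancestor's mutation
        set contained in each descendant's), which is how clone profiles
        derived from a clone tree always are.
        """
        if profiles is None or len(profiles) == 0:
            raise ValueError("no clone profiles given")
        if not 0.0 <= self.ado_rate < 1.0 or not 0.0 <= self.fp_rate < 1.0:
            raise ValueError("ado_rate and fp_rate must be in [0, 1)")
        prof = profiles.astype(int)
        if not prof.isin([0, 1]).all().all():
            raise ValueError("profiles must be binary")
        if self.add_normal and not (prof == 0).all(axis=1).any():
            normal = pd.DataFrame(0, index=["normal"], columns=prof.columns)
            prof = pd.concat([prof, normal])
        self.profiles_ = prof
        return self

    def log_likelihoods(self, matrix: CellGenotypeMatrix) -> pd.DataFrame:
        """Cells x clones log-likelihood table (missing loci contribute 0)."""
        prof = self.profiles_.reindex(columns=matrix.calls.columns)
        if prof.isna().any().any():
            raise KeyError("matrix has loci absent from the fitted profiles")
        g = prof.to_numpy()  # (C, L)
        calls = matrix.calls.to_numpy()  # (N, L)
        a, b = self.ado_rate, self.fp_rate
        # log P(call | g) for the four cases
        lp_mut = np.where(g == 1, np.log(max(1 - a, 1e-300)), np.log(max(b, 1e-300)))
        lp_wt = np.where(g == 1, np.log(max(a, 1e-300)), np.log(max(1 - b, 1e-300)))
        is_mut = (calls == MUTANT).astype(float)
        is_wt = (calls == WILDTYPE).astype(float)
        ll = is_mut @ lp_mut.T + is_wt @ lp_wt.T  # (N, C)
        return pd.DataFrame(ll, index=matrix.calls.index, columns=prof.index)

    def predict_proba(self, matrix: CellGenotypeMatrix) -> pd.DataFrame:
        """Posterior over clones (uniform prior), rows summing to 1."""
        ll = self.log_likelihoods(matrix).to_numpy()
        ll = ll - ll.max(axis=1, keepdims=True)
        post = np.exp(ll)
        post /= post.sum(axis=1, keepdims=True)
        return pd.DataFrame(post, index=matrix.calls.index, columns=self.profiles_.index)

    def predict(self, matrix: CellGenotypeMatrix) -> pd.Series:
        """MAP clone per cell, or ``None`` (unassigned) below the gap."""
        ll = self.log_likelihoods(matrix)
        informative = (matrix.calls != MISSING).sum(axis=1)
        out = []
        arr = ll.to_numpy()
        for i, cell in enumerate(ll.index):
            if informative.iloc[i] == 0:
                out.append(None)
                continue
            order = np.argsort(arr[i])[::-1]
            if len(order) > 1 and arr[i][order[0]] - arr[i][order[1]] < self.gap_min:
                out.append(None)
                continue
            out.append(ll.columns[order[0]])
        return pd.Series(out, index=ll.index, name="clone", dtype=object)


def compartment_comparison(
    fractions_by_compartment: pd.DataFrame,
    present_thresh: float = 0.10,
    absent_thresh: float = 0.02,
) -> pd.DataFrame:
    """Flag loci present in one compartment and absent in another.

    ``fractions_by_compartment`` is loci x compartments (e.g. stem-cell
    mutated fraction next to PB and BM CCFs).  For each ordered compartment
    pair (A, B) a flag ``<A>_only_vs_<B>`` is set when the locus is present
    in A (value >= present_thresh) and absent in B (value <= absent_thresh).
    NaNs never set a flag.  This captures discordance such as a mutation
    detected in sorted stem cells long before whole bone marrow.
    """
    if not 0.0 <= absent_thresh < present_thresh <= 1.0:
        raise ValueError("need 0 <= absent_thresh < present_thresh <= 1")
    comps = list(fractions_by_compartment.columns)
    out = fractions_by_compartment.copy()
    flags = []
    for a in comps:
        for b in comps:
            if a == b:
                continue
            name = f"{a}_only_vs_{b}"
            out[name] = (
                (fractions_by_compartment[a] >= present_thresh)
                & (fractions_by_compartment[b] <= absent_thresh)
                & fractions_by_compartment[a].notna()
                & fractions_by_compartment[b].notna()
            )
            flags.append(name)
    out["discordant"] = out[flags].any(axis=1)
    return out
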