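"""Per-sample mutation summaries.

Burden, region-category tables (exonic+splicing / intronic / intergenic /
others), strand-collapsed substitution spectra with Ti/Tv, and paired
PB-BM VAF concordance.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import RegionIndex, VariantRecord, logger

__all__ = [
    "classify_substitution",
    "spectrum_table",
    "build_category_table",
    "mean_overall_burden",
    "vaf_concordance",
    "burden_per_mb",
    "SPECTRUM_CLASSES",
    "CATEGORY_COLUMNS",
]

#: the six strand-collapsed substitution classes, pyrimidine reference first
SPECTRUM_CLASSES = ("C>A/G>T", "C>G/G>C", "C>T/G>A", "T>A/A>T", "T>C/A>G", "T>G/A>C")
CATEGORY_COLUMNS = ("exonic_splicing", "intronic", "intergenic", "others", "overall")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_TRANSITIONS = {"C>T/G>A", "T>C/A>G"}


def classify_substitution(ref: str, alt: str) -> tuple[str, str]:
    """Strand-collapsed class and mutation type of a single-base substitution.

    Purine-reference substitutions are collapsed onto their pyrimidine
    complement (G>A maps to C>T/G>A).  Returns ``(class, kind)`` with kind
    ``"transition"`` or ``"transversion"``; multi-base alleles return
    ``("indel", "indel")`` and are excluded from spectra.
    """
    ref, alt = ref.upper(), alt.upper()
    if len(ref) != 1 or len(alt) != 1 or ref not in _COMPLEMENT or alt not in _COMPLEMENT:
        return "indel", "indel"
    if ref == alt:
        raise ValueError(f"ref == alt: {ref}")
    if ref in "AG":  # collapse to pyrimidine reference
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    label = f"{ref}>{alt}/{_COMPLEMENT[ref]}>{_COMPLEMENT[alt]}"
    kind = "transition" if label in _TRANSITIONS else "transversion"
    return label, kind


def spectrum_table(records: Sequence[VariantRecord], sample_ids: Sequence[str]) -> pd.DataFrame:
    """Substitution-spectrum counts, fractions and Ti/Tv per sample.

    A variant contributes to a sample's spectrum when it was observed there
    with total depth > 0.  Indels are excluded.
    """
    rows = []
    for sid in sample_ids:
        counts = dict.fromkeys(SPECTRUM_CLASSES, 0)
        ti = tv = 0
        for rec in records:
            obs = rec.observations.get(sid)
            if obs is None or obs[1] == 0:
                continue
            label, kind = classify_substitution(rec.ref, rec.alt)
            if kind == "indel":
                continue
            counts[label] += 1
            if kind == "transition":
                ti += 1
            else:
                tv += 1
        total = ti + tv
        row: dict[str, float] = {"sample_id": sid}
        for cls in SPECTRUM_CLASSES:
            row[cls] = counts[cls]
            row[f"frac {cls}"] = counts[cls] / total if total else float("nan")
        row["ti_tv_ratio"] = ti / tv if tv else float("inf") if ti else float("nan")
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")


def build_category_table(
    records: Sequence[VariantRecord],
    region_index: RegionIndex,
    sample_ids: Sequence[str],
) -> pd.DataFrame:
    """Per-sample region-category counts with an ``overall`` row-sum column.

    A variant counts toward a sample when observed there with depth > 0.
    Splicing and exonic are reported together; positions on chromosomes
    absent from the index fall back to intergenic (warning logged).
    """
    cat_map = {
        "splicing": "exonic_splicing",
        "exonic": "exonic_splicing",
        "intronic": "intronic",
        "intergenic": "intergenic",
        "other": "others",
    }
    table = pd.DataFrame(0, index=list(sample_ids), columns=list(CATEGORY_COLUMNS), dtype=int)
    for rec in records:
        col = cat_map[region_index.classify(rec.chrom, rec.pos)]
        for sid in sample_ids:
            obs = rec.observations.get(sid)
            if obs is None or obs[1] == 0:
                continue
            table.at[sid, col] += 1
            table.at[sid, "overall"] += 1
    bad = table["overall"] != table[list(CATEGORY_COLUMNS[:-1])].sum(axis=1)
    if bad.any():  # defensive; cannot happen with the tally above
        raise AssertionError("category table row-sum invariant violated")
    return table


def mean_overall_burden(table: pd.DataFrame, sample_ids: Sequence[str]) -> tuple[int, Fraction]:
    """Arithmetic mean of ``overall`` counts over samples.

    Returns the mean rounded to the nearest integer and as an exact
    rational, so reported averages are reproducible without float noise.
    """
    if len(sample_ids) == 0:
        raise ValueError("sample_ids must be non-empty")
    missing = [s for s in sample_ids if s not in table.index]
    if missing:
        raise KeyError(f"samples not in table: {missing}")
    counts = [int(table.at[s, "overall"]) for s in sample_ids]
    exact = Fraction(sum(counts), len(counts))
    return round(exact), exact


def vaf_concordance(
    records: Sequence[VariantRecord], sample_a: str, sample_b: str
) -> tuple[float, float, int]:
    """Pearson correlation of VAFs between two samples over shared variants.

    Only variants with total depth > 0 in both samples enter.  The p-value
    comes from the t transform t = r sqrt(n-2) / sqrt(1-r^2) with n-2
    degrees of freedom, two-sided.  Returns ``(r, p, n)``; r is NaN when
    either sample has zero VAF variance.
    """
    xs, ys = [], []
    for rec in records:
        oa, ob = rec.observations.get(sample_a), rec.observations.get(sample_b)
        if oa is None or ob is None or oa[1] == 0 or ob[1] == 0:
            continue
        xs.append(oa[0] / oa[1])
        ys.append(ob[0] / ob[1])
    n = len(xs)
    if n < 3:
        raise ValueError(f"need >= 3 shared variants, got {n}")
    x, y = np.asarray(xs), np.asarray(ys)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan"), n
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        return float(np.sign(r)), 0.0, n
    t = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
    p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return r, p, n


def burden_per_mb(table: pd.DataFrame, callable_genome_size_mb: float = 2800.0) -> pd.Series:
    """Mutations per megabase: overall / callable genome size."""
    if callable_genome_size_mb <= 0:
        raise ValueError(f"callable genome size must be > 0, got {callable_genome_size_mb}")
    return table["overall"] / callable_genome_size_mb
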