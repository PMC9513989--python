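"""Bundled reference tables.

Small published summary statistics from a longitudinal Fanconi-anemia case
that progressed through MDS to AML, used as worked-example inputs and as
fixed points for the burden summaries.
"""

from __future__ import annotations

import pandas as pd

#: Somatic SNV+indel counts per region category for one patient's samples:
#: five FACS-sorted blood-cell populations at the FA stage (B cells,
#: granulocytes, NK cells, monocytes, T cells) and whole bone marrow at
#: three later timepoints (early MDS, late MDS, AML).
_CATEGORY_COUNTS = {
    "2010-B":  {"exonic_splicing": 209, "intronic": 299, "intergenic": 808,  "others": 183},
    "2010-G":  {"exonic_splicing": 4,   "intronic": 285, "intergenic": 817,  "others": 122},
    "2010-K":  {"exonic_splicing": 443, "intronic": 290, "intergenic": 871,  "others": 205},
    "2010-M":  {"exonic_splicing": 179, "intronic": 322, "intergenic": 938,  "others": 166},
    "2010-T":  {"exonic_splicing": 95,  "intronic": 377, "intergenic": 979,  "others": 198},
    "2016-BM": {"exonic_splicing": 14,  "intronic": 367, "intergenic": 898,  "others": 125},
    "2018-BM": {"exonic_splicing": 17,  "intronic": 478, "intergenic": 1193, "others": 162},
    "2019-BM": {"exonic_splicing": 22,  "intronic": 595, "intergenic": 1521, "others": 187},
}

SORTED_CELL_SAMPLES = ("2010-B", "2010-G", "2010-K", "2010-M", "2010-T")


def reference_category_table() -> pd.DataFrame:
    """Region-category mutation counts for the reference longitudinal case.

    Rows are samples, columns the four region categories plus the
    ``overall`` row sum (recomputed here, never stored, so the table always
    satisfies the category-sum invariant by construction).
    """
    df = pd.DataFrame.from_dict(_CATEGORY_COUNTS, orient="index")
    df["overall"] = df.sum(axis=1)
    return df
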