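"""Built-in reference tables.

The eight-donor saliva panel pairs SRCR repeat diploid copy numbers (from
paralogue ratio tests) with salivary protein isoform classes called by
western blot, inferred secretor status, and S. mutans binding activity.  One
PRT assay column could not be recovered for every donor from the published
table; the diploid SRCR total column is complete.  Donor 6 carries the
double-band class-IV isoform.
"""

from __future__ import annotations

import pandas as pd

_SALIVA_PANEL = [
    # sample, cnv1, srcr_diploid_cn, fut2 genotype, isoform, bands (kDa), binding
    ("1", 27, 27, "G/A", "III", "389",     "+"),
    ("2", 24, 24, "A/A", "I",   "345",     "-"),
    ("3", 22, 22, "G/A", "I",   "345",     "-"),
    ("4", 26, 26, "G/G", "II",  "375",     "+"),
    ("5", 24, 24, "G/A", "II",  "375",     "+"),
    ("6", 14, 20, "A/A", "IV",  "287,345", "-"),
    ("7", 25, 25, "G/G", "II",  "375",     "+"),
    ("8", 29, 29, "G/A", "III", "389",     "+"),
]


def saliva_isoform_panel() -> pd.DataFrame:
    """Reference panel of eight saliva donors with matched DNA copy numbers.

    Columns: ``sample``, ``cnv1`` (single-assay PRT diploid estimate),
    ``srcr_diploid_cn``, ``fut2_genotype`` (null allele A, synthetic genotype
    strings consistent with the panel's 2 Se- / 6 Se+ split), ``secretor``,
    ``isoform`` (size class I-IV), ``bands`` (kDa, comma-separated),
    ``binding`` (S. mutans binding on blot).
    """
    from .assoc import infer_secretor

    df = pd.DataFrame(_SALIVA_PANEL,
                      columns=["sample", "cnv1", "srcr_diploid_cn",
                               "fut2_genotype", "isoform", "bands", "binding"])
    df["secretor"] = df["fut2_genotype"].map(infer_secretor)
    return df
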