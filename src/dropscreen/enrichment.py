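"""Per-OTU enrichment scoring across a droplet sort.

The enrichment ratio of a taxon is its relative abundance in the
post-sorting library divided by its relative abundance in the
post-droplet-cultivation (pre-sort) library. Taxa sorted for high activity
should score above 1; inactive taxa below 1. "Amount" is interpreted as
relative abundance, not raw reads: the two libraries are sequenced to
different depths, and raw-count ratios would be depth-confounded.

OTU tables are pandas DataFrames with OTU ids as the index and one column
of counts per sample.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "relative_abundance",
    "enrichment_ratios",
    "classify_enrichment",
    "read_otu_table",
    "write_otu_table",
]


def _sample_counts(table: pd.DataFrame, sample: str | None) -> pd.Series:
    if isinstance(table, pd.Series):
        counts = table
    else:
        if sample is None:
            if table.shape[1] != 1:
                raise ValueError("multi-sample table: specify a sample column")
            sample = table.columns[0]
        counts = table[sample]
    if counts.index.duplicated().any():
        raise ValueError("duplicate OTU ids in table")
    if (counts < 0).any():
        raise ValueError("negative counts in OTU table")
    return counts.astype(float)


def relative_abundance(table, sample: str | None = None) -> pd.Series:
    """Counts normalized to fractions for one sample; sums to 1."""
    counts = _sample_counts(table, sample)
    total = counts.sum()
    if total <= 0:
        raise ValueError(f"sample {sample!r} has zero total count")
    return counts / total


def enrichment_ratios(
    pre,
    post,
    pre_sample: str | None = None,
    post_sample: str | None = None,
    pseudo_fraction: bool = False,
) -> pd.DataFrame:
    """Enrichment ratio of every OTU: post-sort fraction / pre-sort fraction.

    The OTU universe is the union of the two tables (missing = 0 reads).
    OTUs absent from the pre-sort library have an undefined ratio and are
    flagged rather than pseudocounted; pass ``pseudo_fraction=True`` to
    substitute 0.5/depth for zero counts in both samples instead.

    Returns a DataFrame indexed by OTU id with columns ``pre_fraction``,
    ``post_fraction``, ``ratio`` (NaN where undefined) and ``defined``.
    """
    pre_c = _sample_counts(pre, pre_sample)
    post_c = _sample_counts(post, post_sample)
    if len(pre_c.index.intersection(post_c.index)) == 0:
        raise ValueError("pre and post tables share no OTU ids")
    universe = pre_c.index.union(post_c.index)
    pre_c = pre_c.reindex(universe, fill_value=0.0)
    post_c = post_c.reindex(universe, fill_value=0.0)
    if pseudo_fraction:
        pre_c = pre_c.where(pre_c > 0, 0.5)
        post_c = post_c.where(post_c > 0, 0.5)
    pre_f = pre_c / pre_c.sum()
    post_f = post_c / post_c.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = post_f / pre_f
    defined = pre_f > 0
    ratio = ratio.where(defined, np.nan)
    return pd.DataFrame(
        {
            "pre_fraction": pre_f,
            "post_fraction": post_f,
            "ratio": ratio,
            "defined": defined,
        }
    )


def classify_enrichment(results: pd.DataFrame) -> dict[str, int]:
    """Partition OTUs by enrichment status.

    Returns counts ``{"enriched" (>1), "depleted" (<1), "unchanged" (=1),
    "undefined"}``; the four classes are exhaustive and sum to the OTU
    universe size.
    """
    if len(results) == 0:
        raise ValueError("no enrichment results to classify")
    ratio = results["ratio"]
    defined = results["defined"]
    return {
        "enriched": int(((ratio > 1) & defined).sum()),
        "depleted": int(((ratio < 1) & defined).sum()),
        "unchanged": int(((ratio == 1) & defined).sum()),
        "undefined": int((~defined).sum()),
    }


def read_otu_table(path) -> pd.DataFrame:
    """Read a TSV OTU table (OTU rows, sample columns, header row)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_otu_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t")
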