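"""TPM quantification and detection summaries.

Counts are converted to transcripts-per-million (TPM): each gene's count is
divided by its effective length, and the resulting rates are scaled so each
sample sums to one million.  Detection summaries count genes in a subset
(e.g. the TF catalog) whose whole-embryo mean TPM clears a ladder of
thresholds; the strictness at each rung (``> 0``, ``>= 1``, ``> 10``,
``>= 1000``) mirrors the conventional mixed wording of such summaries.
The TF-vs-all-genes comparison bins log10 TPM and reports a two-sample
Kolmogorov-Smirnov distance as the similarity summary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Region labels for the five gastrula dissection fragments plus whole embryo.
REGIONS = ("AC", "DMZ", "LMZ", "VMZ", "VEG")
WHOLE_EMBRYO = "WE"


@dataclass
class ExpressionSet:
    """Gene x sample counts with effective lengths and sample metadata.

    ``metadata`` is indexed by sample and carries either a ``region`` column
    (regional design) or a ``timepoint`` column (time course), plus
    ``replicate``.  TPM is derived lazily and cached.
    """

    counts: pd.DataFrame
    eff_length: pd.Series
    metadata: pd.DataFrame
    _tpm: Optional[pd.DataFrame] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValueError(f"duplicated gene ID in counts: {dup}")
        missing = self.counts.index.difference(self.eff_length.index)
        if len(missing):
            raise ValueError(f"genes without effective length: {list(missing[:5])}")
        if (self.eff_length.loc[self.counts.index] <= 0).any():
            raise ValueError("effective lengths must be positive")
        if not self.counts.columns.equals(self.metadata.index):
            missing = self.counts.columns.difference(self.metadata.index)
            if len(missing):
                raise ValueError(f"samples without metadata: {list(missing)}")
            self.metadata = self.metadata.loc[self.counts.columns]

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    @property
    def tpm(self) -> pd.DataFrame:
        if self._tpm is None:
            self._tpm = compute_tpm(self.counts, self.eff_length)
        return self._tpm

    def samples_for_region(self, region: str) -> list[str]:
        if "region" not in self.metadata.columns:
            raise ValueError("ExpressionSet has no regional metadata")
        return list(self.metadata.index[self.metadata["region"] == region])

    def region_mean_tpm(self, regions: Sequence[str] = REGIONS) -> pd.DataFrame:
        """Gene x region matrix of replicate-mean TPM."""
        cols = {}
        for r in regions:
            s = self.samples_for_region(r)
            if not s:
                raise ValueError(f"no samples for region {r}")
            cols[r] = self.tpm[s].mean(axis=1)
        return pd.DataFrame(cols)


def compute_tpm(counts: pd.DataFrame, eff_length: pd.Series) -> pd.DataFrame:
    """Transcripts per million.

    ``tpm[g, s] = 1e6 * (counts[g, s] / L[g]) / sum_g'(counts[g', s] / L[g'])``.
    An all-zero sample yields an all-zero column with a warning.
    """
    lengths = eff_length.loc[counts.index].to_numpy(dtype=float)
    if (lengths <= 0).any():
        raise ValueError("effective lengths must be positive")
    rate = counts.to_numpy(dtype=float) / lengths[:, None]
    denom = rate.sum(axis=0)
    zero_cols = denom == 0
    if zero_cols.any():
        logger.warning("compute_tpm: %d all-zero sample(s); TPM set to 0", int(zero_cols.sum()))
        denom = np.where(zero_cols, 1.0, denom)
    tpm = 1e6 * rate / denom
    return pd.DataFrame(tpm, index=counts.index, columns=counts.columns)


def detection_summary(
    tpm: pd.DataFrame,
    gene_subset: Optional[Sequence[str]] = None,
    samples: Optional[Sequence[str]] = None,
) -> dict[str, int]:
    """Detection counts at the standard TPM threshold ladder.

    Replicate TPMs over ``samples`` (default: all columns) are averaged per
    gene; the summary counts genes with mean TPM ``> 0``, ``>= 1``, ``> 10``
    and ``>= 1000``.
    """
    sub = tpm if gene_subset is None else tpm.loc[list(gene_subset)]
    if samples is not None:
        sub = sub[list(samples)]
    if sub.empty:
        return {"detected": 0, "tpm_ge_1": 0, "tpm_gt_10": 0, "tpm_ge_1000": 0}
    mean = sub.mean(axis=1)
    return {
        "detected": int((mean > 0).sum()),
        "tpm_ge_1": int((mean >= 1).sum()),
        "tpm_gt_10": int((mean > 10).sum()),
        "tpm_ge_1000": int((mean >= 1000).sum()),
    }


def distribution_compare(
    tpm_all: pd.Series,
    tf_genes: Sequence[str],
    bin_width: float = 0.25,
    background_genes: Optional[Sequence[str]] = None,
) -> dict:
    """Compare the TF expression-level distribution with all genes.

    Expressed genes' (TPM > 0) log10 TPM values are binned on a fixed grid
    of ``bin_width``-wide bins, each histogram normalized to its own total,
    and a two-sample Kolmogorov-Smirnov distance summarizes how far the TF
    distribution departs from the background (every gene in ``tpm_all``
    unless ``background_genes`` restricts it).
    """
    bg = tpm_all if background_genes is None else tpm_all.loc[list(background_genes)]
    all_vals = np.log10(bg[bg > 0].to_numpy(dtype=float))
    tf_series = tpm_all.loc[list(tf_genes)]
    tf_vals = np.log10(tf_series[tf_series > 0].to_numpy(dtype=float))
    if len(all_vals) < 2 or len(tf_vals) < 2:
        raise ValueError("need at least 2 expressed genes in each set")
    lo = np.floor(min(all_vals.min(), tf_vals.min()) / bin_width) * bin_width
    hi = np.ceil(max(all_vals.max(), tf_vals.max()) / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    hist_all, _ = np.histogram(all_vals, bins=edges)
    hist_tf, _ = np.histogram(tf_vals, bins=edges)
    ks = stats.ks_2samp(tf_vals, all_vals)
    return {
        "bin_edges": edges,
        "freq_all": hist_all / hist_all.sum(),
        "freq_tf": hist_tf / hist_tf.sum(),
        "ks_distance": float(ks.statistic),
        "ks_pvalue": float(ks.pvalue),
        "n_all": len(all_vals),
        "n_tf": len(tf_vals),
    }
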