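"""Gene-expression quantification, differential expression, and
DEG x DAS x TF integration.

Expression is summarized as FPKM (fragments per kilobase of exonic length
per million mapped fragments); a gene is *expressed* when FPKM >= 0.1 in
at least one sample.  Differential expression between conditions A and B
uses a negative-binomial Wald test on median-of-ratios-normalized counts
(the classic size-factor normalization), with a method-of-moments,
trend-moderated dispersion estimate; genes with |log2FC| > 1 and BH
FDR < 0.05 (strict) are DEGs.

Integration intersects DEGs with DAS genes (genes owning at least one
differentially spliced event) and with a user-supplied transcription
factor list, yielding the DE-DAS and DE-DAS-TF sets.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import ValidationError

logger = logging.getLogger(__name__)


def compute_fpkm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """FPKM matrix: count * 1e9 / (gene_length * sample_total)."""
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()
        raise ValidationError(f"missing gene lengths for {missing[:5]}")
    if (lengths <= 0).any():
        raise ValidationError("gene lengths must be positive")
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        raise ValidationError("zero library size in at least one sample")
    return counts.mul(1e9).div(lengths, axis=0).div(totals, axis=1)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (reference = per-gene geometric mean)."""
    log_counts = np.log(counts.replace(0, np.nan))
    log_geo = log_counts.mean(axis=1)
    usable = log_geo.notna()
    if not usable.any():
        raise ValidationError("no gene with nonzero counts in every sample")
    ratios = log_counts.loc[usable].sub(log_geo[usable], axis=0)
    sf = np.exp(ratios.median(axis=0))
    return sf / np.exp(np.log(sf).mean())


def deg_test(
    counts: pd.DataFrame,
    conditions: dict[str, str],
    cond_a: str = "A",
    cond_b: str = "B",
) -> pd.DataFrame:
    """Per-gene NB Wald test of condition B vs A on normalized counts.

    Dispersion (variance = mu + alpha*mu^2, clipped to [1e-8, 10]) is
    estimated by method of moments per gene and then pooled into a common
    mean dispersion used in the Wald variance: at 3+3 replicates the
    gene-wise moment estimate is so unstable that genes with accidentally
    small sample variance would otherwise dominate the false positives.
    Gene-wise values are reported alongside.  log2FC uses a
    pseudo-count of 1 on the normalized condition means.  All-zero genes
    are excluded.
    """
    samples_a = sorted(s for s, c in conditions.items() if c == cond_a)
    samples_b = sorted(s for s, c in conditions.items() if c == cond_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValidationError("deg_test requires >= 2 replicates per condition")
    counts = counts[samples_a + samples_b]
    nonzero = counts.sum(axis=1) > 0
    if (~nonzero).any():
        logger.info("deg_test: excluded %d all-zero gene(s)", int((~nonzero).sum()))
    counts = counts.loc[nonzero]
    sf = size_factors(counts)
    norm = counts.div(sf, axis=1)
    na, nb = len(samples_a), len(samples_b)
    A, B = norm[samples_a].to_numpy(), norm[samples_b].to_numpy()
    mu_a, mu_b = A.mean(axis=1), B.mean(axis=1)

    # pooled within-condition residual variance -> MoM dispersion
    ss = ((A - mu_a[:, None]) ** 2).sum(axis=1) + ((B - mu_b[:, None]) ** 2).sum(axis=1)
    var_pooled = ss / (na + nb - 2)
    mu_pooled = (na * mu_a + nb * mu_b) / (na + nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (var_pooled - mu_pooled) / np.square(mu_pooled)
    alpha_gene = np.where(np.isfinite(alpha), alpha, 0.0)
    alpha_gene = np.clip(alpha_gene, 1e-8, 10.0)
    alpha = np.full_like(alpha_gene, alpha_gene.mean())
    alpha = np.maximum(alpha, 1e-8)

    pc = 1.0
    lfc_nat = np.log(mu_b + pc) - np.log(mu_a + pc)
    var_mean_a = (mu_a + alpha * mu_a**2) / na
    var_mean_b = (mu_b + alpha * mu_b**2) / nb
    se = np.sqrt(var_mean_a / np.square(mu_a + pc) + var_mean_b / np.square(mu_b + pc))
    z = np.where(se > 0, lfc_nat / se, 0.0)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "base_mean": mu_pooled,
            "mean_a": mu_a,
            "mean_b": mu_b,
            "dispersion": alpha,
            "dispersion_genewise": alpha_gene,
            "log2fc": lfc_nat / math.log(2),
            "stat": z,
            "p_value": np.clip(pvals, 0, 1),
        },
        index=counts.index,
    )


def call_degs(
    results: pd.DataFrame,
    log2fc_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """BH adjustment and strict-threshold DEG calling (adds fdr/is_deg)."""
    results = results.copy()
    if results.empty:
        results["fdr"] = []
        results["is_deg"] = []
        return results
    _, fdr, _, _ = multipletests(results["p_value"].to_numpy(), method="fdr_bh")
    results["fdr"] = fdr
    results["is_deg"] = (results["log2fc"].abs() > log2fc_threshold) & (
        results["fdr"] < fdr_threshold
    )
    n_up = int((results["is_deg"] & (results["log2fc"] > 0)).sum())
    n_down = int((results["is_deg"] & (results["log2fc"] < 0)).sum())
    logger.info("call_degs: %d DEGs (%d up, %d down in B vs A)", n_up + n_down, n_up, n_down)
    return results


def expressed_flags(fpkm: pd.DataFrame, threshold: float = 0.1) -> pd.Series:
    """A gene is expressed when FPKM >= threshold in at least one sample."""
    return (fpkm >= threshold).any(axis=1)


def integrate(
    degs: pd.DataFrame,
    das_results: pd.DataFrame,
    event_gene_map: dict[str, str],
    tf_list: set[str] | None = None,
) -> pd.DataFrame:
    """DEG x DAS x TF integration table, one row per gene in ``degs``.

    DAS genes are the unique genes owning >= 1 differentially spliced
    event via ``event_gene_map``; DE-DAS genes are DEGs among them;
    DE-DAS-TF genes are additionally in ``tf_list``.
    """
    tf_list = tf_list or set()
    das_gene_set: set[str] = set()
    if not das_results.empty:
        for _, row in das_results[das_results["is_das"]].iterrows():
            gene = event_gene_map.get(row["event_id"])
            if gene is None:
                logger.warning("integrate: event %s maps to no gene, excluded", row["event_id"])
                continue
            das_gene_set.add(gene)

    out = degs.copy()
    out["is_das_gene"] = out.index.isin(das_gene_set)
    out["is_tf"] = out.index.isin(tf_list)
    out["is_de_das"] = out["is_deg"] & out["is_das_gene"]
    out["is_de_das_tf"] = out["is_de_das"] & out["is_tf"]
    n = out[["is_deg", "is_das_gene", "is_de_das", "is_de_das_tf"]].sum()
    logger.info(
        "integrate: %d DEGs, %d DAS genes (in table), %d DE-DAS, %d DE-DAS-TF",
        n["is_deg"], n["is_das_gene"], n["is_de_das"], n["is_de_das_tf"],
    )
    return out
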