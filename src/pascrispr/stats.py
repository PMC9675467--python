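"""Allele-specific expression tests and permutation gene-set enrichment.

ASE: at each heterozygous exonic SNP, reads carrying the mutant-haplotype
allele and reads carrying the normal-haplotype allele are counted per
clone; control and treated clone groups are compared per site with a
classical two-sample Student t test (pooled variance, two-tailed), and the
per-site p values are Bonferroni-corrected within each allele class
separately (the mutant-allele panel and the normal-allele panel form
separate families).

Enrichment: a candidate gene set's score is the sum of its members'
significance values (-log10 of an FDR-adjusted p from an upstream
differential-expression analysis); the null is built by repeatedly drawing
equally sized gene sets uniformly without replacement from the expressed
universe, and the empirical p uses the standard +1 correction, so the
smallest attainable p is 1/(n_permutations + 1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

ASE_GROUPS = ("control", "treated")
ASE_ALLELES = ("mutant", "normal")


def validate_ase_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format ASE count matrix and normalise dtypes.

    Required columns: ``site, clone, group, allele, count`` with groups in
    {control, treated}, alleles in {mutant, normal} and non-negative
    integer counts.
    """
    required = {"site", "clone", "group", "allele", "count"}
    missing = required - set(matrix.columns)
    if missing:
        raise ValueError(f"ASE matrix missing columns: {sorted(missing)}")
    if not set(matrix["group"]) <= set(ASE_GROUPS):
        raise ValueError(f"group labels must be in {ASE_GROUPS}")
    if not set(matrix["allele"]) <= set(ASE_ALLELES):
        raise ValueError(f"allele labels must be in {ASE_ALLELES}")
    counts = matrix["count"].to_numpy()
    if (counts < 0).any() or not np.allclose(counts, np.round(counts)):
        raise ValueError("counts must be non-negative integers")
    for g in ASE_GROUPS:
        if not (matrix["group"] == g).any():
            raise ValueError(f"ASE matrix has no {g} clones")
    return matrix


@dataclass
class AseSiteResult:
    site: str
    mean_control: float
    mean_treated: float
    t_statistic: float
    p_value: float
    p_bonferroni: float
    significant: bool
    degenerate: bool = False


def ase_site_test(
    matrix: pd.DataFrame,
    allele: str,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-site control-vs-treated t tests for one allele class.

    Pooled-variance (classical Student) two-tailed t by default; set
    ``equal_var=False`` for Welch. Bonferroni correction multiplies each
    nominal p by the number of sites tested for this allele class, capped
    at 1. Zero-variance degeneracies: equal constant groups give t=0, p=1;
    unequal constant groups are flagged degenerate with p reported as 0.
    """
    matrix = validate_ase_matrix(matrix)
    if allele not in ASE_ALLELES:
        raise ValueError(f"allele must be one of {ASE_ALLELES}")
    sub = matrix[matrix["allele"] == allele]
    sites = sorted(sub["site"].unique())
    n_sites = len(sites)
    results: list[AseSiteResult] = []
    for site in sites:
        at = sub[sub["site"] == site]
        ctrl = at.loc[at["group"] == "control", "count"].to_numpy(dtype=float)
        trt = at.loc[at["group"] == "treated", "count"].to_numpy(dtype=float)
        if len(ctrl) < 2 or len(trt) < 2:
            raise ValueError(f"site {site}: need >=2 clones per group")
        degenerate = False
        if ctrl.var(ddof=1) == 0 and trt.var(ddof=1) == 0:
            if ctrl.mean() == trt.mean():
                t, p = 0.0, 1.0
            else:
                t, p = float("inf"), 0.0
                degenerate = True
                logger.warning(
                    "ase_site_test: site %s has zero variance in both groups with "
                    "unequal means; t undefined, p reported as 0", site,
                )
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                t, p = sps.ttest_ind(ctrl, trt, equal_var=equal_var)
            t, p = float(t), float(p)
        p_bonf = min(1.0, p * n_sites)
        results.append(
            AseSiteResult(
                site=site,
                mean_control=float(ctrl.mean()),
                mean_treated=float(trt.mean()),
                t_statistic=t,
                p_value=p,
                p_bonferroni=p_bonf,
                significant=bool(p_bonf < alpha),
                degenerate=degenerate,
            )
        )
    return pd.DataFrame([r.__dict__ for r in results])


@dataclass
class EnrichmentResult:
    """Permutation gene-set enrichment outcome."""

    observed_score: float
    n_permutations: int
    n_null_ge_observed: int
    empirical_p: float
    set_size: int
    universe_size: int
    seed: int
    n_dropped: int = 0  # candidate genes absent from the expressed universe


def gene_set_score(table: pd.Series, gene_set: list[str] | set[str]) -> tuple[float, list[str]]:
    """Sum of significance values over the set's members in the universe.

    ``table`` maps gene id -> significance value (non-negative, finite).
    Genes outside the universe are dropped with a logged count; an empty
    intersection is an error. Returns (score, members actually used).
    """
    vals = table.to_numpy(dtype=float)
    if not np.isfinite(vals).all() or (vals < 0).any():
        raise ValueError("significance values must be finite and non-negative")
    members = [g for g in gene_set if g in table.index]
    n_dropped = len(set(gene_set)) - len(set(members))
    if n_dropped:
        logger.info("gene_set_score: dropped %d genes absent from the expressed universe",
                    n_dropped)
    if not members:
        raise ValueError("gene set has empty intersection with the expressed universe")
    return float(table.loc[members].sum()), members


def permutation_enrichment(
    table: pd.Series,
    gene_set: list[str] | set[str],
    n_permutations: int = 10_000,
    seed: int = 0,
    chunk_size: int = 1_000,
) -> EnrichmentResult:
    """Empirical enrichment p by uniform sampling without replacement.

    Null sets of size ``|gene_set ∩ universe|`` are drawn uniformly without
    replacement from the universe; the empirical p is
    ``(1 + #{null >= observed}) / (1 + n_permutations)``. Deterministic
    given ``seed``.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    observed, members = gene_set_score(table, gene_set)
    n_dropped = len(set(gene_set)) - len(set(members))
    k = len(members)
    scores = table.to_numpy(dtype=float)
    n = len(scores)
    if k > n:
        raise ValueError("gene set larger than the universe")
    rng = np.random.default_rng(seed)
    count = 0
    done = 0
    while done < n_permutations:
        m = min(chunk_size, n_permutations - done)
        # random keys -> first-k argpartition == uniform sample w/o replacement
        keys = rng.random((m, n))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
        null_scores = scores[idx].sum(axis=1)
        count += int((null_scores >= observed).sum())
        done += m
    p = (1 + count) / (1 + n_permutations)
    return EnrichmentResult(
        observed_score=observed,
        n_permutations=n_permutations,
        n_null_ge_observed=count,
        empirical_p=p,
        set_size=k,
        universe_size=n,
        seed=seed,
        n_dropped=n_dropped,
    )
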