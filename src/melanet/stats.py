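"""Statistical core: two-group expression re-analysis, DE overlays, and the
Monte-Carlo overlap-enrichment test.

The expression re-analysis mirrors the array comparison of normal skin
vs primary melanoma: per-gene Welch t-test on log2 intensities, Bonferroni
family-wise correction (strict ``p < alpha/m``), and nested fold-change
classes FC2/FC3/FC4 (|fold change| strictly greater than 2, 3, 4) assigned
only to Bonferroni-significant genes.

The overlap-enrichment test asks whether a query gene set (e.g. a
fold-change class, or the genes differentially expressed after drug
treatment) shares more members with the network model than random gene
lists of the same size: ``n_sims`` lists are drawn uniformly without
replacement from the universe, the null overlap distribution is summarized
by its sample mean and SD, and significance is the upper normal tail
``p = 1 - Phi((k - mu) / sigma)`` — the same convention as R's
``pnorm(k, mu, sigma, lower.tail = FALSE)``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .gwas import normalize_symbol

log = logging.getLogger(__name__)

__all__ = [
    "GeneStat",
    "OverlapResult",
    "welch_test",
    "bonferroni_mask",
    "fc_classes",
    "analyze_expression",
    "overlap_enrichment",
    "overlay_de",
    "hypergeom_term_enrichment",
    "read_expression",
    "read_de_table",
]

FC_THRESHOLDS = (2.0, 3.0, 4.0)


@dataclass(frozen=True)
class OverlapResult:
    """Monte-Carlo overlap-enrichment outcome."""

    n_overlap: int
    n_query: int
    n_model: int
    n_universe: int
    n_sims: int
    null_mean: float
    null_sd: float
    p_norm: float
    rng_seed: int


# ---------------------------------------------------------------------------
# Welch t / Bonferroni / fold-change classes

def welch_test(x, y) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test: returns (t, df, two-sided p).

    Degenerate case: both groups with zero variance and equal means gives
    (0, df, 1).  Groups must have at least two observations each.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("Welch test needs >= 2 observations per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if x.mean() == y.mean():
            return 0.0, float(x.size + y.size - 2), 1.0
        raise ValueError("zero variance in both groups with unequal means")
    res = sps.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def bonferroni_mask(p_values, alpha: float = 0.05) -> tuple[float, np.ndarray]:
    """Family-wise threshold alpha/m and the strict ``p < threshold`` mask."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to correct")
    threshold = alpha / p.size
    return threshold, p < threshold


def fc_classes(
    log2fc,
    significant,
    thresholds: tuple[float, ...] = FC_THRESHOLDS,
    scale: str = "log2",
) -> pd.DataFrame:
    """Nested fold-change class flags FC2/FC3/FC4 for significant genes.

    ``scale="log2"`` applies the thresholds to the log2 fold change
    (|log2FC| > k); ``scale="linear"`` applies them to the linear ratio
    (2**|log2FC| > k).  Classes are strict (>) and only significant genes
    are classed, so FC4 is a subset of FC3 is a subset of FC2.
    """
    lfc = np.asarray(log2fc, dtype=float)
    sig = np.asarray(significant, dtype=bool)
    if scale == "log2":
        magnitude = np.abs(lfc)
    elif scale == "linear":
        magnitude = 2.0 ** np.abs(lfc)
    else:
        raise ValueError(f"unknown fc scale {scale!r}")
    out = {}
    for k in thresholds:
        out[f"FC{k:g}"] = sig & (magnitude > k)
    return pd.DataFrame(out)


def analyze_expression(
    matrix: pd.DataFrame,
    groups: pd.Series,
    alpha: float = 0.05,
    fc_thresholds: tuple[float, ...] = FC_THRESHOLDS,
    fc_scale: str = "log2",
) -> pd.DataFrame:
    """Per-gene Welch t / Bonferroni / FC-class table for a two-group matrix.

    ``matrix`` is genes x samples, linear-scale intensities (must be
    positive); ``groups`` maps sample name to one of exactly two labels.
    Group 1 is the lexicographically smaller label (the reference, e.g.
    "normal"); log2FC = log2(mean_group2 / mean_group1) of linear means and
    the Welch test runs on log2-transformed intensities.
    """
    groups = groups.astype(str)
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    g1 = [s for s in matrix.columns if groups.get(s) == labels[0]]
    g2 = [s for s in matrix.columns if groups.get(s) == labels[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("need >= 2 samples per group")
    if matrix.index.duplicated().any():
        raise ValueError("duplicate gene ids in expression matrix")
    x1 = matrix[g1].to_numpy(dtype=float)
    x2 = matrix[g2].to_numpy(dtype=float)
    if (x1 <= 0).any() or (x2 <= 0).any():
        raise ValueError("intensities must be positive for log2 transform")
    log2fc = np.log2(x2.mean(axis=1) / x1.mean(axis=1))
    l1, l2 = np.log2(x1), np.log2(x2)
    res = sps.ttest_ind(l2, l1, axis=1, equal_var=False)
    t, df, p = res.statistic, res.df, res.pvalue
    # degenerate rows (zero variance both groups, equal means) -> t=0, p=1
    flat = np.isnan(t)
    t = np.where(flat, 0.0, t)
    p = np.where(flat, 1.0, p)
    threshold, sig = bonferroni_mask(p, alpha)
    classes = fc_classes(log2fc, sig, fc_thresholds, fc_scale)
    out = pd.DataFrame(
        {
            "gene": matrix.index,
            "log2fc": log2fc,
            "t_stat": t,
            "welch_df": df,
            "p_value": p,
            "significant": sig,
        }
    )
    out = pd.concat([out.reset_index(drop=True), classes.reset_index(drop=True)], axis=1)
    out.attrs["bonferroni_threshold"] = threshold
    out.attrs["n_tests"] = len(out)
    out.attrs["group1"], out.attrs["group2"] = labels
    return out


# ---------------------------------------------------------------------------
# Monte-Carlo overlap enrichment

def overlap_enrichment(
    query,
    model,
    universe,
    n_sims: int = 100_000,
    rng_seed: int = 0,
    _chunk: int | None = None,
) -> OverlapResult:
    """Monte-Carlo overlap-enrichment test of ``query`` against ``model``.

    Each of ``n_sims`` simulations draws ``|query|`` genes uniformly without
    replacement from ``universe`` and records its overlap with ``model``;
    the observed overlap k = |query & model| is scored against the fitted
    normal upper tail 1 - Phi((k - mu) / sigma) with sample mu and sigma
    (ddof=1).  Query/model members outside the universe are logged and
    intersected away.  With sigma = 0 the p degenerates to 0 if k > mu else
    1, with a warning.
    """
    query = {normalize_symbol(s) for s in query}
    model = {normalize_symbol(s) for s in model}
    universe_list = sorted({normalize_symbol(s) for s in universe})
    universe_set = set(universe_list)
    for name, s in (("query", query), ("model", model)):
        stray = s - universe_set
        if stray:
            log.warning("%d %s genes outside universe intersected away", len(stray), name)
    query &= universe_set
    model &= universe_set
    n_universe, n_query, n_model = len(universe_list), len(query), len(model)
    if n_universe == 0:
        raise ValueError("empty universe")
    if n_query > n_universe:
        raise ValueError("query larger than universe")
    k = len(query & model)

    model_mask = np.zeros(n_universe, dtype=bool)
    idx_of = {g: i for i, g in enumerate(universe_list)}
    for g in model:
        model_mask[idx_of[g]] = True

    rng = np.random.default_rng(rng_seed)
    # chunk size capped so each random-key block stays ~64 MB
    chunk = _chunk or max(16, min(n_sims, 8_000_000 // max(n_universe, 1)))
    sims = np.empty(n_sims, dtype=np.int64)
    done = 0
    while done < n_sims:
        size = min(chunk, n_sims - done)
        if n_query == 0:
            sims[done : done + size] = 0
        else:
            # uniform without-replacement draws: smallest-key top-n trick
            keys = rng.random((size, n_universe))
            picks = np.argpartition(keys, n_query - 1, axis=1)[:, :n_query]
            sims[done : done + size] = model_mask[picks].sum(axis=1)
        done += size
    mu = float(sims.mean())
    sd = float(sims.std(ddof=1)) if n_sims > 1 else 0.0
    if sd == 0.0:
        warnings.warn("degenerate null distribution (sd = 0)", RuntimeWarning)
        p = 0.0 if k > mu else 1.0
    else:
        p = float(sps.norm.sf(k, loc=mu, scale=sd))
    return OverlapResult(
        n_overlap=k,
        n_query=n_query,
        n_model=n_model,
        n_universe=n_universe,
        n_sims=n_sims,
        null_mean=mu,
        null_sd=sd,
        p_norm=p,
        rng_seed=rng_seed,
    )


def overlay_de(
    de_table: pd.DataFrame, model, padj_max: float = 0.05
) -> tuple[set[str], float]:
    """Model genes significantly altered in a DE table (adjusted p < cutoff).

    Returns the overlap set and its fraction of the model.  ``de_table``
    needs columns ``gene`` and ``padj``.
    """
    model = {normalize_symbol(s) for s in model}
    if not model:
        raise ValueError("empty model gene set")
    sig = {
        normalize_symbol(g)
        for g, padj in zip(de_table["gene"], de_table["padj"])
        if float(padj) < padj_max
    }
    overlap = model & sig
    return overlap, len(overlap) / len(model)


# ---------------------------------------------------------------------------
# Offline term enrichment (hypergeometric + BH) — pipeline plumbing

def hypergeom_term_enrichment(
    query, annotations: dict[str, set], universe
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of a query against term gene sets.

    ``annotations`` maps term id (or "id|name") to its gene set (a subset of
    the universe).  Returns a term table with exact upper-tail p, BH-adjusted
    p, term_size and intersection_size — the same shape consumed by the
    semantic-grouping stage.
    """
    universe = {normalize_symbol(s) for s in universe}
    if not universe:
        raise ValueError("empty universe")
    query = {normalize_symbol(s) for s in query} & universe
    rows = []
    for term in sorted(annotations):
        genes = {normalize_symbol(s) for s in annotations[term]} & universe
        k = len(query & genes)
        # P(X >= k) with X ~ Hypergeom(N=|U|, K=|term|, n=|query|)
        p = float(sps.hypergeom.sf(k - 1, len(universe), len(genes), len(query)))
        term_id, _, name = term.partition("|")
        rows.append(
            {
                "term_id": term_id,
                "term_name": name or term_id,
                "p_value": min(p, 1.0),
                "term_size": len(genes),
                "intersection_size": k,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["adjusted_p_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
    else:
        df["adjusted_p_value"] = pd.Series(dtype=float)
    return df


# ---------------------------------------------------------------------------
# Table readers

def read_expression(matrix_path, groups_path) -> tuple[pd.DataFrame, pd.Series]:
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    gdf = pd.read_csv(groups_path, sep="\t", dtype=str)
    groups = pd.Series(gdf["group"].values, index=gdf["sample"].values)
    return matrix, groups


def read_de_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    required = {"gene", "log2fc", "pvalue", "padj"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    for col in ("pvalue", "padj"):
        vals = df[col].astype(float)
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError(f"{col} outside [0, 1]")
    return df
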