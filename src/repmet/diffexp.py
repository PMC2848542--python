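"""Probe-level differential expression and probe -> gene summarization.

Two-group differential expression on an already-normalized log2 expression matrix
(rows = probes/probe-sets, columns = samples).  The default test is the
empirical-Bayes moderated t: per-probe sample variances are shrunk toward a common
prior whose hyperparameters (prior df d0 and prior variance s0^2) are estimated by
matching moments of the log sample variances, and the reference distribution is a
t with d + d0 degrees of freedom.  An unequal-variance Welch t is available as a
plain alternative.

Probe-set scores are collapsed to genes by the top-rank-tier rule: restrict to the
probes of the best (minimal) rank tier, copy a single probe's values, otherwise
take the median p and median logfc.
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

logger = logging.getLogger(__name__)

PROBE_COLUMNS = ("probe_id", "gene_id", "rank_tier", "p", "logfc")
GENE_COLUMNS = ("gene_id", "p", "logfc", "direction")


# ---------------------------------------------------------------------------------
# empirical-Bayes variance shrinkage (moment matching on log variances)


def _trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)

def fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Estimate (d0, s0^2) of the scaled-F prior for sample variances.

    Matches the mean and variance of log(s2) against the theoretical moments of a
    log scaled-F variate, using digamma/trigamma identities; returns
    (np.inf, geometric-mean-based scale) when the observed spread is no larger
    than the chi-square sampling noise.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if not ok.any():
        raise ValueError("all sample variances are zero; cannot fit prior")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    n = e.size
    evar = float(((e - emean) ** 2).sum() / max(n - 1, 1)) - float(
        special.polygamma(1, df / 2.0)
    )
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_2 = float(
            np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
        )
    else:
        d0 = np.inf
        s0_2 = float(np.exp(emean))
    return d0, s0_2


def moderated_t_pvalues(
    diff: np.ndarray,
    s2: np.ndarray,
    n1: int,
    n2: int,
    d0: float | None = None,
    s0_2: float | None = None,
) -> tuple[np.ndarray, float, float]:
    """Two-sided p-values for mean differences with shrunken variances.

    ``s2`` are pooled per-probe variances on d = n1+n2-2 df.  Returns
    (p-values, d0, s0^2); hyperparameters are estimated unless supplied.
    """
    d = n1 + n2 - 2
    if d0 is None or s0_2 is None:
        d0, s0_2 = fit_f_dist(s2, d)
    if np.isinf(d0):
        s2_tilde = np.full_like(np.asarray(s2, dtype=float), s0_2)
        df_total = np.inf
    else:
        s2_tilde = (d0 * s0_2 + d * s2) / (d0 + d)
        df_total = d + d0
    se = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / np.where(se > 0, se, 1.0), 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return np.clip(p, np.finfo(float).tiny, 1.0), float(d0), float(s0_2)


# ---------------------------------------------------------------------------------
# per-probe differential expression


def differential_expression(
    expr: pd.DataFrame,
    groups: Mapping[str, str],
    contrast: tuple[str, str],
    method: str = "moderated",
) -> pd.DataFrame:
    """Per-probe two-sided p and log2 fold-change for ``contrast = (label1, label2)``.

    ``expr``: probes x samples log-scale matrix (index = probe ids, columns =
    sample ids).  ``logfc = mean(label1) - mean(label2)``.  Returns a DataFrame
    with columns (probe_id, p, logfc).
    """
    label1, label2 = contrast
    cols1 = [s for s in expr.columns if groups.get(s) == label1]
    cols2 = [s for s in expr.columns if groups.get(s) == label2]
    if len(cols1) < 2 or len(cols2) < 2:
        raise ValueError(
            f"each group needs >=2 samples; got {len(cols1)} for {label1!r}, "
            f"{len(cols2)} for {label2!r}"
        )
    x1 = expr[cols1].to_numpy(dtype=float)
    x2 = expr[cols2].to_numpy(dtype=float)
    if not (np.isfinite(x1).all() and np.isfinite(x2).all()):
        raise ValueError("expression matrix contains non-finite values")
    n1, n2 = x1.shape[1], x2.shape[1]
    diff = x1.mean(axis=1) - x2.mean(axis=1)

    if method == "moderated":
        ss = ((x1 - x1.mean(1, keepdims=True)) ** 2).sum(1) + (
            (x2 - x2.mean(1, keepdims=True)) ** 2
        ).sum(1)
        s2 = ss / (n1 + n2 - 2)
        if not (s2 > 0).any():
            warnings.warn("all probes have zero variance; p set to 1")
            p = np.ones_like(diff)
        else:
            p, d0, s0_2 = moderated_t_pvalues(diff, s2, n1, n2)
            logger.debug("moderated test: d0=%.4g s0^2=%.4g", d0, s0_2)
    elif method == "welch":
        with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.ttest_ind(x1, x2, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
        zero_var = (x1.var(axis=1) == 0) & (x2.var(axis=1) == 0)
        bad = zero_var | ~np.isfinite(p)
        if bad.any():
            warnings.warn(
                f"{int(bad.sum())} zero-variance probes under welch; p set to 1"
            )
            p[bad] = 1.0
    else:
        raise ValueError(f"unknown method {method!r}")

    return pd.DataFrame(
        {"probe_id": expr.index.astype(str), "p": p, "logfc": diff}
    ).reset_index(drop=True)


def attach_probe_map(
    probe_scores: pd.DataFrame, probe_map: pd.DataFrame
) -> pd.DataFrame:
    """Join per-probe scores with a probe -> gene map.

    ``probe_map`` columns: probe_id, gene_id and optionally rank_tier (default 1
    when absent).  Probes missing from the map are dropped with a log message.
    """
    pm = probe_map.copy()
    if "rank_tier" not in pm.columns:
        pm["rank_tier"] = 1
    merged = probe_scores.merge(
        pm[["probe_id", "gene_id", "rank_tier"]], on="probe_id", how="inner"
    )
    dropped = len(probe_scores) - len(merged)
    if dropped:
        logger.info("dropped %d probes without gene mapping", dropped)
    return merged[list(PROBE_COLUMNS)]


# ---------------------------------------------------------------------------------
# probe -> gene summarization


def summarize_probes(scores: pd.DataFrame) -> pd.DataFrame:
    """Collapse probe scores to one score per gene via the top-tier median rule.

    Per gene: restrict to probes of the minimal rank_tier; a single probe's p and
    logfc are copied, several probes give the median p and median logfc.  The
    direction is the sign of the gene logfc; an exact zero breaks to "down" with a
    warning so the output is deterministic.
    """
    required = {"probe_id", "gene_id", "p", "logfc"}
    if not required.issubset(scores.columns):
        raise ValueError(f"probe scores need columns {sorted(required)}")
    df = scores.copy()
    if "rank_tier" not in df.columns:
        df["rank_tier"] = 1

    rows = []
    zero_ties = 0
    for gene_id, sub in df.groupby("gene_id", sort=True):
        top = sub[sub["rank_tier"] == sub["rank_tier"].min()]
        p = float(top["p"].median())
        logfc = float(top["logfc"].median())
        if logfc > 0:
            direction = "up"
        else:
            if logfc == 0:
                zero_ties += 1
            direction = "down"
        rows.append((str(gene_id), p, logfc, direction))
    if zero_ties:
        warnings.warn(
            f"{zero_ties} genes with logfc exactly 0 assigned direction 'down'"
        )
    return pd.DataFrame(rows, columns=list(GENE_COLUMNS))


# ---------------------------------------------------------------------------------
# TSV carriers


def read_expression_tsv(path) -> pd.DataFrame:
    """Expression matrix TSV: first column probe_id, header = sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def read_probe_map_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "gene_id": str})
    if not {"probe_id", "gene_id"}.issubset(df.columns):
        raise ValueError("probe map needs columns probe_id, gene_id[, rank_tier]")
    return df


def read_groups_tsv(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample", "group"}.issubset(df.columns):
        raise ValueError("groups table needs columns sample, group")
    return dict(zip(df["sample"], df["group"]))


def read_gene_scores_tsv(path) -> pd.DataFrame:
    """Precomputed gene scores: gene_id, p, logfc[, direction]."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if not {"gene_id", "p"}.issubset(df.columns):
        raise ValueError("gene scores need columns gene_id, p[, logfc, direction]")
    if "logfc" not in df.columns:
        df["logfc"] = 0.0
    if "direction" not in df.columns:
        df["direction"] = np.where(df["logfc"] > 0, "up", "down")
    bad = ~((df["p"] > 0) & (df["p"] <= 1))
    if bad.any():
        raise ValueError(f"{int(bad.sum())} gene p-values outside (0,1]")
    return df[list(GENE_COLUMNS)]


def write_gene_scores_tsv(gene_scores: pd.DataFrame, path) -> None:
    gene_scores.to_csv(path, sep="\t", index=False, float_format="%.10g")
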