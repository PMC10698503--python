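"""Regulated phosphosite calling, specificity classes, and interactor calling.

Quantitative phosphoproteomics compares inhibitor-treated lysates against
controls in two independent arms (one per phosphatase).  A site is called
regulated in an arm when its phospho-signal *increases* upon inhibition by
more than a fold-change gate with a significant Welch t-test:

    regulated  <=>  p < alpha  AND  log2(inhibitor / control) > log2fc_min

Defaults alpha = 0.05 and log2fc_min = 0.58 (1.5-fold).  Specificity classes
partition dually-evaluated sites into {PP1, B55, ambiguous, unregulated}.

Label-free pulldown/proximity tables use the same machinery with a 2-fold
gate, after downshifted-normal imputation of missing values (the standard
Perseus-style scheme: per sample, missing entries are drawn from
Normal(mu - downshift*sigma, (width*sigma)^2)).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

logger = logging.getLogger(__name__)

ALPHA_DEFAULT = 0.05
LOG2FC_DEFAULT = 0.58  # 1.5-fold
INTERACTOR_FOLD_DEFAULT = 2.0

CLASSES = ("PP1", "B55", "ambiguous", "unregulated")


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize_tmt(raw: pd.DataFrame) -> pd.DataFrame:
    """Channel-total normalization followed by log2.

    Each channel (column) is divided by its total over the mean channel
    total, which equalizes channel sums, then log2-transformed.  Zero or
    negative channel totals are an error naming the channel.
    """
    totals = raw.sum(axis=0)
    bad = totals[totals <= 0]
    if not bad.empty:
        raise InputError(f"non-positive channel totals: {list(bad.index)}")
    factors = totals / totals.mean()
    adjusted = raw.div(factors, axis=1)
    if (adjusted <= 0).any().any():
        raise InputError("non-positive intensities cannot be log2-transformed")
    return np.log2(adjusted)


# ---------------------------------------------------------------------------
# Regulated-site calling
# ---------------------------------------------------------------------------

def welch_ttest(x, y):
    """Two-sample two-tailed Welch t-test; returns ``(t, df, p)``.

    Degenerate case: zero variance in both groups with equal means gives
    p = 1 (no evidence of difference).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise InputError("Welch test requires >= 2 replicates per group")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, float(len(x) + len(y) - 2), 1.0
        return np.inf, float(len(x) + len(y) - 2), 0.0
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def call_regulated(
    inhibitor,
    control,
    alpha: float = ALPHA_DEFAULT,
    log2fc_min: float = LOG2FC_DEFAULT,
):
    """Regulation call for one site in one arm on log2 intensities.

    Returns ``(log2fc, p, flag)`` where log2fc = mean(inhibitor) -
    mean(control); the conjunctive gate requires both significance and a
    directional fold change (increase upon inhibition).
    """
    inhibitor = np.asarray(inhibitor, dtype=float)
    control = np.asarray(control, dtype=float)
    log2fc = float(inhibitor.mean() - control.mean())
    _, _, p = welch_ttest(inhibitor, control)
    return log2fc, p, bool(p < alpha and log2fc > log2fc_min)


def _call_table(inh: np.ndarray, ctrl: np.ndarray, alpha: float, log2fc_min: float):
    """Vectorized regulation call over a (sites x replicates) pair of arrays."""
    log2fc = inh.mean(axis=1) - ctrl.mean(axis=1)
    res = stats.ttest_ind(inh, ctrl, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    # both-constant, equal-mean rows: no evidence of difference
    degenerate = (inh.var(axis=1, ddof=1) == 0) & (ctrl.var(axis=1, ddof=1) == 0)
    p = np.where(degenerate & (log2fc == 0), 1.0, p)
    p = np.where(degenerate & (log2fc != 0), 0.0, p)
    flag = (p < alpha) & (log2fc > log2fc_min)
    return log2fc, p, flag


def classify_specificity(regulated_pp1: bool, regulated_b55: bool) -> str:
    """Four-way specificity class from the two per-arm calls."""
    if regulated_pp1 and regulated_b55:
        return "ambiguous"
    if regulated_pp1:
        return "PP1"
    if regulated_b55:
        return "B55"
    return "unregulated"


def classify_sites(
    sites: pd.DataFrame,
    alpha: float = ALPHA_DEFAULT,
    log2fc_min: float = LOG2FC_DEFAULT,
) -> pd.DataFrame:
    """Call both arms on a wide-format site table and assign classes.

    Replicate columns follow the convention ``{arm}_{group}_r{i}`` with arm in
    {pp1, b55} and group in {inhib, ctrl}, e.g. ``pp1_inhib_r1``.  Requires
    >= 2 replicates per group.  Returns the input plus per-arm log2fc, p, and
    regulated flags, and the class column.
    """
    out = sites.copy()
    for arm in ("pp1", "b55"):
        inh_cols = sorted(c for c in sites.columns if c.startswith(f"{arm}_inhib_r"))
        ctl_cols = sorted(c for c in sites.columns if c.startswith(f"{arm}_ctrl_r"))
        if len(inh_cols) < 2 or len(ctl_cols) < 2:
            raise InputError(f"arm {arm!r} needs >= 2 replicates per group")
        inh = sites[inh_cols].to_numpy(dtype=float)
        ctl = sites[ctl_cols].to_numpy(dtype=float)
        log2fc, p, flag = _call_table(inh, ctl, alpha, log2fc_min)
        out[f"{arm}_log2fc"] = log2fc
        out[f"{arm}_p"] = p
        out[f"{arm}_regulated"] = flag
    out["class"] = [
        classify_specificity(a, b)
        for a, b in zip(out["pp1_regulated"], out["b55_regulated"])
    ]
    return out


def summary_statistics(calls: pd.DataFrame) -> dict:
    """Counts, acceptor distributions, and cross-arm overlap for classified calls.

    Expects the output of :func:`classify_sites`; acceptor percentages use the
    ``acceptor`` column when present.
    """
    n = len(calls)
    counts = {cls: int((calls["class"] == cls).sum()) for cls in CLASSES}
    out = {"n_sites": n, "class_counts": counts}

    n_reg_pp1 = int(calls["pp1_regulated"].sum())
    n_reg_b55 = int(calls["b55_regulated"].sum())
    n_both = counts["ambiguous"]
    n_reg_any = n_reg_pp1 + n_reg_b55 - n_both
    out["regulated_pp1"] = n_reg_pp1
    out["regulated_b55"] = n_reg_b55
    out["regulated_both"] = n_both
    out["overlap_fraction_of_regulated"] = (n_both / n_reg_any) if n_reg_any else 0.0

    if "acceptor" in calls.columns:
        acceptors = {}
        for cls in CLASSES:
            sub = calls.loc[calls["class"] == cls, "acceptor"]
            total = len(sub)
            acceptors[cls] = {
                a: (100.0 * (sub == a).sum() / total if total else 0.0)
                for a in ("S", "T", "Y")
            }
        out["acceptor_pct"] = acceptors
    return out


# ---------------------------------------------------------------------------
# Label-free interactors
# ---------------------------------------------------------------------------

def impute_missing(
    table: pd.DataFrame,
    width_factor: float = 0.3,
    downshift: float = 1.8,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Downshifted-normal imputation of missing log intensities, per sample.

    For each column with observed mean mu and SD sigma, missing entries are
    drawn from Normal(mu - downshift*sigma, (width_factor*sigma)^2).
    Deterministic under a fixed seed; a table without missing values is
    returned unchanged.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = table.copy()
    for col in out.columns:
        v = out[col]
        missing = v.isna()
        if not missing.any():
            continue
        observed = v.dropna().to_numpy(dtype=float)
        if len(observed) < 10:
            raise InputError(f"sample {col!r} has {len(observed)} observed values; need >= 10")
        mu, sigma = observed.mean(), observed.std(ddof=1)
        draws = rng.normal(mu - downshift * sigma, width_factor * sigma, int(missing.sum()))
        out.loc[missing, col] = draws
    return out


def call_interactors(
    table: pd.DataFrame,
    bait: str,
    method: str = "AP-MS",
    fold_min: float = INTERACTOR_FOLD_DEFAULT,
    alpha: float = ALPHA_DEFAULT,
) -> pd.DataFrame:
    """Call bait-specific interactors from an imputed log2 intensity table.

    ``table`` is indexed by protein_id with columns ``bait_r{i}`` and
    ``ctrl_r{i}`` (log2 scale).  A protein is an interactor when enriched at
    least ``fold_min``-fold over control with p < alpha (two-tailed t-test).
    """
    bait_cols = sorted(c for c in table.columns if c.startswith("bait_r"))
    ctrl_cols = sorted(c for c in table.columns if c.startswith("ctrl_r"))
    if len(bait_cols) < 2 or len(ctrl_cols) < 2:
        raise InputError("interactor calling needs >= 2 replicates per group")
    if table[bait_cols + ctrl_cols].isna().any().any():
        raise InputError("missing values present; run impute_missing first")
    b = table[bait_cols].to_numpy(dtype=float)
    c = table[ctrl_cols].to_numpy(dtype=float)
    log2fc, p, _ = _call_table(b, c, alpha, np.log2(fold_min))
    flag = (p < alpha) & (log2fc >= np.log2(fold_min))
    return pd.DataFrame(
        {
            "protein_id": table.index,
            "bait": bait,
            "method": method,
            "log2_enrichment": log2fc,
            "p_value": p,
            "interactor": flag,
        }
    ).reset_index(drop=True)


def interactome_union(calls: list) -> pd.DataFrame:
    """Union of interactor calls across methods for one bait.

    A protein belongs to the bait's interactome if any method called it.
    """
    merged = pd.concat(calls, ignore_index=True)
    grouped = merged.groupby(["protein_id", "bait"], sort=True)["interactor"].any()
    return grouped.reset_index()


def join_sites_interactome(
    calls: pd.DataFrame,
    interactors: pd.DataFrame,
    site_class: str,
    bait: str,
    id_map: dict | None = None,
) -> dict:
    """Count regulated sites of one class residing on a bait's interactors.

    ``id_map`` optionally translates site-table protein ids into the
    interactome's namespace; unmapped ids are logged, excluded, and counted.
    Returns counts and the per-protein listing, plus the complement (regulated
    sites on non-interactor proteins) for motif contrasts.
    """
    reg = calls[calls["class"] == site_class].copy()
    if id_map is not None:
        mapped = reg["protein_id"].map(id_map)
        unmapped = int(mapped.isna().sum())
        if unmapped:
            logger.info("join: %d regulated sites on unmapped proteins excluded", unmapped)
        reg = reg[mapped.notna()].assign(protein_id=mapped.dropna())
    else:
        unmapped = 0
    members = set(
        interactors.loc[
            (interactors["bait"] == bait) & (interactors["interactor"]), "protein_id"
        ]
    )
    on = reg[reg["protein_id"].isin(members)]
    off = reg[~reg["protein_id"].isin(members)]
    return {
        "bait": bait,
        "site_class": site_class,
        "n_regulated": len(reg),
        "n_on_interactors": len(on),
        "n_off_interactors": len(off),
        "n_unmapped": unmapped,
        "sites_on_interactors": on,
        "sites_off_interactors": off,
    }
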