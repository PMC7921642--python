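"""Per-stage differential expression against a pooled control group.

Each non-control stage is contrasted against the pooled control samples with
a two-sample pooled-variance t-test, optionally moderated by an empirical-
Bayes squeeze of the per-gene variances toward a common prior:

    s2_tilde_g = (d0 * s0^2 + d_g * s2_g) / (d0 + d_g)

with the prior degrees of freedom d0 and prior variance s0^2 estimated across
genes by method-of-moments on the log variances (Smyth-style fit of a scaled
F distribution).  The moderated t uses d0 + d_g degrees of freedom; d0 = 0
recovers the ordinary pooled t exactly.

Expression values are assumed log2-scale, so the signed fold change between
group means m1, m0 is ``2**(m1-m0)`` when the stage is up (reported >= 1) and
``-2**(m0-m1)`` when down (reported <= -1): the conventional signed linear
fold change where down-regulation reads as < -1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .errors import ContrastError, DegenerateDataError, ValidationError
from .synthetic import StageDesign

__all__ = [
    "fit_contrast",
    "bh_adjust",
    "filter_and_merge",
    "fit_all_contrasts",
    "collapse_to_symbols",
    "ModerationFit",
    "signed_fold_change",
]


@dataclass(frozen=True)
class ModerationFit:
    """Empirical-Bayes prior fitted across genes: d0 (may be inf) and s0^2."""

    d0: float
    s02: float


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(75):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < 1e-12 * x:
            break
    return x


def fit_moderation(s2: np.ndarray, df: float) -> ModerationFit:
    """Method-of-moments fit of the variance prior (d0, s0^2).

    Matches the classic moderated-t hyperparameter estimate: with
    z_g = log s2_g, e_g = z_g - digamma(df/2) + log(df/2) has mean
    log s0^2 - digamma(d0/2) + log(d0/2) and excess variance trigamma(d0/2)
    over trigamma(df/2).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise DegenerateDataError("fewer than two genes with positive variance")
    z = np.log(s2[ok])
    e = z - float(special.digamma(df / 2.0)) + math.log(df / 2.0)
    emean = float(e.mean())
    n = e.size
    evar = float(((e - emean) ** 2).sum() / (n - 1))
    excess = evar * (n - 1) / n - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        return ModerationFit(d0=math.inf, s02=math.exp(emean))
    half_d0 = _trigamma_inverse(excess)
    if not math.isfinite(half_d0):
        return ModerationFit(d0=math.inf, s02=math.exp(emean))
    s02 = math.exp(emean + float(special.digamma(half_d0)) - math.log(half_d0))
    return ModerationFit(d0=2.0 * half_d0, s02=s02)


def signed_fold_change(mean_stage: np.ndarray, mean_control: np.ndarray) -> np.ndarray:
    """Signed linear fold change from log2-scale group means."""
    diff = np.asarray(mean_stage, float) - np.asarray(mean_control, float)
    return np.where(diff >= 0, 2.0 ** diff, -(2.0 ** (-diff)))


def fit_contrast(
    expr: pd.DataFrame,
    design: StageDesign,
    stage: str,
    moderated: bool = True,
) -> pd.DataFrame:
    """Differential expression of one stage versus the pooled control group.

    Returns a table indexed like ``expr`` with columns mean_stage,
    mean_control, signed_fc, t, p, adj_p; the fitted prior is stored in
    ``.attrs`` (keys ``contrast``, ``d0``, ``s02``).  ``moderated=False``
    gives the ordinary pooled two-sample t (equivalently d0 = 0).
    """
    if stage in design.control_stages:
        raise ContrastError(f"stage {stage!r} is part of the control group")
    if stage not in design.stage_order:
        raise ContrastError(f"unknown stage {stage!r}")
    stage_cols = [s for s in expr.columns if design.assignment.get(s) == stage]
    ctrl_cols = [s for s in expr.columns if design.assignment.get(s) in design.control_stages]
    n1, n0 = len(stage_cols), len(ctrl_cols)
    if n1 < 2 or n0 < 2:
        raise ContrastError(
            f"contrast {stage!r}: needs >= 2 samples per group (got {n1} stage, {n0} control)"
        )
    x1 = expr[stage_cols].to_numpy(dtype=float)
    x0 = expr[ctrl_cols].to_numpy(dtype=float)
    if not (np.isfinite(x1).all() and np.isfinite(x0).all()):
        raise ValidationError("expression matrix contains non-finite values")

    m1, m0 = x1.mean(axis=1), x0.mean(axis=1)
    v1 = x1.var(axis=1, ddof=1)
    v0 = x0.var(axis=1, ddof=1)
    dg = float(n1 + n0 - 2)
    s2 = ((n1 - 1) * v1 + (n0 - 1) * v0) / dg
    if np.all(s2 == 0):
        raise DegenerateDataError(f"contrast {stage!r}: zero variance across all genes")

    if moderated:
        prior = fit_moderation(s2, dg)
        if math.isinf(prior.d0):
            s2_tilde = np.full_like(s2, prior.s02)
            df_total = math.inf
        else:
            s2_tilde = (prior.d0 * prior.s02 + dg * s2) / (prior.d0 + dg)
            df_total = prior.d0 + dg
    else:
        prior = ModerationFit(d0=0.0, s02=float("nan"))
        s2_tilde = s2
        df_total = dg

    se = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n0))
    diff = m1 - m0
    t = np.zeros_like(diff)
    nz = se > 0
    t[nz] = diff[nz] / se[nz]
    inf_mask = ~nz & (diff != 0)  # zero residual variance but a real shift
    t[inf_mask] = np.sign(diff[inf_mask]) * np.inf
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, 0.0, 1.0)

    table = pd.DataFrame(
        {
            "mean_stage": m1,
            "mean_control": m0,
            "signed_fc": signed_fold_change(m1, m0),
            "t": t,
            "p": p,
            "adj_p": bh_adjust(p),
        },
        index=expr.index.copy(),
    )
    table.attrs["contrast"] = stage
    table.attrs["d0"] = prior.d0
    table.attrs["s02"] = prior.s02
    table.attrs["df"] = df_total
    return table


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fit_all_contrasts(
    expr: pd.DataFrame, design: StageDesign, moderated: bool = True
) -> dict[str, pd.DataFrame]:
    """One DGE table per non-control stage, keyed by stage label."""
    return {
        stage: fit_contrast(expr, design, stage, moderated=moderated)
        for stage in design.non_control_stages
    }


def filter_and_merge(
    tables: dict[str, pd.DataFrame] | list[pd.DataFrame],
    p_thresh: float = 0.05,
    fc_thresh: float = 1.5,
    use_adjusted: bool = True,
) -> pd.DataFrame:
    """Threshold each contrast and union the survivors.

    A gene passes a contrast when its (adjusted, by default) p-value is below
    ``p_thresh`` and its |signed fold change| exceeds ``fc_thresh``.  Returns
    one row per gene in the union, with a ``contrasts`` provenance column
    (comma-joined contrast labels in stage order) and ``n_contrasts``.
    """
    if isinstance(tables, dict):
        items = list(tables.items())
    else:
        items = [(t.attrs.get("contrast", str(i)), t) for i, t in enumerate(tables)]
    if not items:
        raise ValidationError("filter_and_merge: empty table list")
    universe = items[0][1].index
    hits: dict[str, list[str]] = {}
    for name, table in items:
        if not table.index.equals(universe):
            raise ValidationError("filter_and_merge: tables cover different gene universes")
        pcol = table["adj_p"] if use_adjusted else table["p"]
        keep = (pcol < p_thresh) & (table["signed_fc"].abs() > fc_thresh)
        for gene in table.index[keep]:
            hits.setdefault(gene, []).append(str(name))
    genes = [g for g in universe if g in hits]
    return pd.DataFrame(
        {
            "gene": genes,
            "contrasts": [",".join(hits[g]) for g in genes],
            "n_contrasts": [len(hits[g]) for g in genes],
        }
    )


def collapse_to_symbols(table: pd.DataFrame, probe_map: dict[str, str]) -> pd.DataFrame:
    """Collapse probe-level DGE rows to gene symbols, keeping max |t| per symbol.

    Probes absent from the map are dropped; the number dropped is recorded in
    ``.attrs['unmapped_probes']``.
    """
    mapped = table.loc[[p for p in table.index if p in probe_map]].copy()
    mapped["symbol"] = [probe_map[p] for p in mapped.index]
    order = mapped["t"].abs().sort_values(ascending=False).index
    best = mapped.loc[order].drop_duplicates(subset="symbol", keep="first")
    out = best.set_index("symbol").sort_index()
    out.attrs.update(table.attrs)
    out.attrs["unmapped_probes"] = len(table) - len(mapped)
    return out
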