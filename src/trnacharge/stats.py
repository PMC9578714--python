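"""Normalization, isodecoder aggregation, and replicate statistics.

Counts are depth-normalized per sample by a coefficient equal to the mean
classified read count across samples divided by that sample's classified
count (the charged fraction is invariant to this scaling; it only makes
count outputs comparable).  Gene-level counts are summed within each
isodecoder and the fraction charged is Σcharged / (Σcharged + Σuncharged)
per sample.  Condition means ± sample SD are reported per isodecoder, and
condition contrasts use Welch's unpaired t-test with Benjamini–Hochberg
FDR adjustment across isodecoders within each contrast.

Also provides the qPCR ΔΔCt helper: relative abundance = 2^(−ΔΔCt) with a
reference gene as internal control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


class StatsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# normalization & aggregation

def normalize(
    counts: pd.DataFrame, basis: str = "classified"
) -> tuple[pd.DataFrame, pd.Series]:
    """Scale per-gene counts so every sample has the cross-sample mean total.

    ``counts`` is the long ChargeCountTable (sample, gene, n_charged,
    n_uncharged, n_undetermined).  The coefficient denominator is the
    classified (charged + uncharged) total by default, or the mapped total
    with ``basis="mapped"``.  Returns the normalized table (float counts)
    and the per-sample coefficients.
    """
    if counts.empty:
        raise StatsError("empty count table")
    if basis not in ("classified", "mapped"):
        raise StatsError(f"unknown normalization basis {basis!r}")
    cols = ["n_charged", "n_uncharged"]
    if basis == "mapped":
        cols = cols + ["n_undetermined"]
    totals = counts.groupby("sample")[cols].sum().sum(axis=1)
    zero = totals[totals == 0]
    if not zero.empty:
        raise StatsError(
            f"sample(s) with zero {basis} reads: {', '.join(zero.index)}"
        )
    coeff = totals.mean() / totals
    out = counts.copy()
    c = out["sample"].map(coeff)
    for col in ("n_charged", "n_uncharged", "n_undetermined"):
        out[col] = out[col] * c
    return out, coeff


def fraction_charged(
    counts: pd.DataFrame, isodecoder_map: Mapping[str, str]
) -> pd.DataFrame:
    """Per-sample per-isodecoder fraction charged.

    Sums (normalized) charged and uncharged counts over the genes of each
    isodecoder; cells with a zero denominator are missing (NaN), never 0.
    Returns a sample × isodecoder DataFrame.
    """
    df = counts.copy()
    unknown = set(df["gene"]) - set(isodecoder_map)
    if unknown:
        raise StatsError(f"genes without an isodecoder: {sorted(unknown)}")
    df["isodecoder"] = df["gene"].map(isodecoder_map)
    g = df.groupby(["sample", "isodecoder"])[["n_charged", "n_uncharged"]].sum()
    denom = g["n_charged"] + g["n_uncharged"]
    frac = g["n_charged"].where(denom > 0) / denom.where(denom > 0)
    return frac.unstack("isodecoder")


def summarize_replicates(
    fractions: pd.DataFrame, design: pd.DataFrame
) -> pd.DataFrame:
    """Condition mean ± sample SD (ddof=1) per isodecoder over replicates.

    ``design`` maps sample → condition (columns ``sample``, ``condition``).
    Missing cells are excluded; ``n`` reports the replicates actually used,
    and SD is NaN when fewer than two remain.
    """
    cond_of = design.set_index("sample")["condition"]
    long = fractions.stack(future_stack=True).rename("fraction").reset_index()
    long.columns = ["sample", "isodecoder", "fraction"]
    long["condition"] = long["sample"].map(cond_of)
    g = long.dropna(subset=["fraction"]).groupby(["condition", "isodecoder"])
    out = g["fraction"].agg(mean="mean", sd=lambda x: x.std(ddof=1), n="count")
    return out.reset_index()


# ---------------------------------------------------------------------------
# tests

@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float
    degenerate: bool = False


def welch_test(a: Sequence[float], b: Sequence[float]) -> WelchResult:
    """Welch's unpaired two-sample t-test (two-sided).

    t = (m_a − m_b) / sqrt(s_a²/n_a + s_b²/n_b), degrees of freedom by
    Welch–Satterthwaite, p from Student's t.  Degenerate zero-variance
    groups: equal means → (t=0, p=1); differing means → p=0, flagged.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise StatsError("welch_test needs at least two values per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return WelchResult(0.0, float(na + nb - 2), 1.0)
        return WelchResult(math.copysign(math.inf, a.mean() - b.mean()),
                           float(na + nb - 2), 0.0, degenerate=True)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return WelchResult(float(t), float(df), float(min(p, 1.0)))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved.

    q_(i) = min_{j>=i}( p_(j) · m / j ), capped at 1.  NaNs are passed
    through and do not count toward m.
    """
    p = np.asarray(p_values, dtype=float)
    mask = ~np.isnan(p)
    vals = p[mask]
    if ((vals < 0) | (vals > 1)).any():
        raise StatsError("p-values must lie in [0, 1]")
    m = len(vals)
    out = np.full(p.shape, np.nan)
    if m:
        order = np.argsort(vals, kind="stable")
        ranked = vals[order] * m / np.arange(1, m + 1)
        q = np.minimum.accumulate(ranked[::-1])[::-1]
        q = np.minimum(q, 1.0)
        adj = np.empty(m)
        adj[order] = q
        out[mask] = adj
    return out


def compare_conditions(
    fractions: pd.DataFrame,
    design: pd.DataFrame,
    contrasts: Sequence[tuple[str, str]],
) -> pd.DataFrame:
    """Welch test per isodecoder for each (treatment, control) contrast.

    BH adjustment is applied across isodecoders *within* each contrast.
    Isodecoders with fewer than two non-missing replicates in either group
    get NaN statistics (and are excluded from the BH family).
    """
    cond_of = design.set_index("sample")["condition"]
    rows = []
    for treat, ctrl in contrasts:
        sa = [s for s in fractions.index if cond_of.get(s) == treat]
        sb = [s for s in fractions.index if cond_of.get(s) == ctrl]
        if not sa or not sb:
            raise StatsError(f"contrast {treat}:{ctrl} names unknown condition(s)")
        ps = []
        recs = []
        for iso in fractions.columns:
            a = fractions.loc[sa, iso].dropna().to_numpy()
            b = fractions.loc[sb, iso].dropna().to_numpy()
            if len(a) < 2 or len(b) < 2:
                recs.append((iso, np.nan, np.nan, np.nan,
                             a.mean() if len(a) else np.nan,
                             b.mean() if len(b) else np.nan))
                ps.append(np.nan)
                continue
            r = welch_test(a, b)
            recs.append((iso, r.t, r.df, r.p, a.mean(), b.mean()))
            ps.append(r.p)
        padj = bh_adjust(ps)
        for (iso, t, df, p, ma, mb), q in zip(recs, padj):
            rows.append(
                dict(contrast=f"{treat}:{ctrl}", isodecoder=iso,
                     mean_treatment=ma, mean_control=mb,
                     delta=ma - mb, t=t, df=df, p=p, p_adj=q)
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# qPCR

def ddct(measurements: pd.DataFrame, control_group: str) -> pd.DataFrame:
    """Relative transcript abundance by the ΔΔCt method.

    ``measurements`` columns: sample, group, ct_target, ct_reference.
    ΔCt = Ct_target − Ct_reference per sample; ΔΔCt = ΔCt − mean ΔCt of
    the control group; relative abundance = 2^(−ΔΔCt).
    """
    req = {"sample", "group", "ct_target", "ct_reference"}
    missing = req - set(measurements.columns)
    if missing:
        raise StatsError(f"measurements missing column(s) {sorted(missing)}")
    df = measurements.copy()
    if df[["ct_target", "ct_reference"]].isna().any().any():
        raise StatsError("missing Ct value")
    if control_group not in set(df["group"]):
        raise StatsError(f"control group {control_group!r} absent")
    df["dct"] = df["ct_target"] - df["ct_reference"]
    ref = df.loc[df["group"] == control_group, "dct"].mean()
    df["ddct"] = df["dct"] - ref
    df["relative_abundance"] = 2.0 ** (-df["ddct"])
    return df
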