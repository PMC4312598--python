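"""Per-gene two-way factorial ANOVA with per-effect FDR control.

Each gene's log2 expression is modeled with fixed °Brix (4 categorical
levels) and tissue (2 levels) effects plus their interaction.  Complete,
balanced genes are fit with the classical sums-of-squares decomposition,
vectorized across all genes at once; genes left unbalanced by replicate QC
fall back to a per-gene Type II fit.  Raw p-values per effect are adjusted
across genes with the Benjamini-Hochberg step-up, separately within each of
the three effect columns.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import ExpressionExperiment, condition_label

EFFECTS = ("brix", "tissue", "interaction")
STATUS_OK = "ok"
STATUS_NO_INTERACTION = "no_interaction"
STATUS_DROPPED = "dropped_degenerate"

# F-test p-values indistinguishable from zero are reported at the smallest
# positive normal double rather than 0, keeping -log10(p) finite.
P_FLOOR = np.finfo(float).tiny


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaNs pass through.

    ``adj_(i) = min_{j >= i} p_(j) m / j`` over the sorted non-NaN values,
    capped at 1, with m the number of tested (non-NaN) hypotheses.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pm = p[mask]
    if ((pm < 0) | (pm > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pm.size
    if m == 0:
        return out
    order = np.argsort(pm, kind="stable")
    ranked = pm[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    restored = np.empty(m)
    restored[order] = adj
    out[mask] = restored
    return out


def _classical_anova(Y: np.ndarray, a: int, b: int, n: int) -> dict[str, np.ndarray]:
    """Vectorized balanced two-way ANOVA.

    ``Y`` has shape (genes, a, b, n): brix level x tissue x replicate.
    Returns F and p per effect plus mean squares.
    """
    grand = Y.mean(axis=(1, 2, 3))
    cell = Y.mean(axis=3)                                  # g x a x b
    A = Y.mean(axis=(2, 3))                                # g x a
    B = Y.mean(axis=(1, 3))                                # g x b
    ss_a = b * n * ((A - grand[:, None]) ** 2).sum(axis=1)
    ss_b = a * n * ((B - grand[:, None]) ** 2).sum(axis=1)
    inter = cell - A[:, :, None] - B[:, None, :] + grand[:, None, None]
    ss_ab = n * (inter ** 2).sum(axis=(1, 2))
    ss_e = ((Y - cell[:, :, :, None]) ** 2).sum(axis=(1, 2, 3))
    df_a, df_b, df_ab, df_e = a - 1, b - 1, (a - 1) * (b - 1), a * b * (n - 1)
    ms_e = ss_e / df_e
    res = {"ss_total": ss_a + ss_b + ss_ab + ss_e, "ms_error": ms_e}
    for name, ss, df in (("brix", ss_a, df_a), ("tissue", ss_b, df_b),
                         ("interaction", ss_ab, df_ab)):
        # a zero effect SS is an exact null F even when ms_e is zero; a
        # positive SS over zero error variance is an infinite F (p at floor)
        with np.errstate(divide="ignore", invalid="ignore"):
            F = np.where(ss <= 0, 0.0, (ss / df) / ms_e)
        p = stats.f.sf(F, df, df_e)
        res[f"F_{name}"] = F
        res[f"p_{name}"] = np.maximum(p, P_FLOOR)
    return res


def _type2_anova_single(y: np.ndarray, brix: np.ndarray, tissue: np.ndarray
                        ) -> tuple[dict[str, float], str]:
    """Type II two-way ANOVA for one gene with missing replicates.

    Uses OLS model comparisons: each main effect is tested against the
    additive model containing the other main effect; the interaction
    against the additive model.  Equals the classical decomposition when
    the data are balanced.
    """
    import statsmodels.api as sm

    def design(cols):
        mats = []
        for f in cols:
            levels = np.unique(f)
            mats.append(np.column_stack([(f == l).astype(float)
                                         for l in levels[1:]]))
        full = [np.ones((y.size, 1))] + mats
        return np.hstack(full)

    fa = brix.astype(str)
    fb = tissue
    fab = np.char.add(np.char.add(fa, ":"), fb)
    levels_a, levels_b = np.unique(fa), np.unique(fb)
    if levels_a.size < 2 or levels_b.size < 2:
        return {}, STATUS_DROPPED

    cells = pd.Series(fab).value_counts()
    full_grid = levels_a.size * levels_b.size
    has_all_cells = len(cells) == full_grid

    def rss(X):
        fit = sm.OLS(y, X).fit()
        return fit.ssr, y.size - np.linalg.matrix_rank(X)

    X_add = design([fa, fb])
    X_a = design([fa])
    X_b = design([fb])
    rss_add, df_add = rss(X_add)
    rss_a, _ = rss(X_a)
    rss_b, _ = rss(X_b)

    out: dict[str, float] = {}
    if has_all_cells and (cells >= 2).all():
        X_full = design([fa, fb, fab])
        rss_full, df_full = rss(X_full)
        if df_full <= 0 or rss_full <= 0:
            return {}, STATUS_DROPPED
        ms_e = rss_full / df_full
        df_ab = (levels_a.size - 1) * (levels_b.size - 1)
        F = ((rss_add - rss_full) / df_ab) / ms_e
        out["F_interaction"] = F
        out["p_interaction"] = max(stats.f.sf(F, df_ab, df_full), P_FLOOR)
        err_rss, err_df = rss_full, df_full
        status = STATUS_OK
    else:
        # interaction not estimable: marginal tests against the additive fit
        if df_add <= 0 or rss_add <= 0:
            return {}, STATUS_DROPPED
        err_rss, err_df = rss_add, df_add
        out["F_interaction"] = np.nan
        out["p_interaction"] = np.nan
        status = STATUS_NO_INTERACTION
    ms_e = err_rss / err_df
    for name, rss_red, df_eff in (("brix", rss_b, levels_a.size - 1),
                                  ("tissue", rss_a, levels_b.size - 1)):
        F = ((rss_red - rss_add) / df_eff) / ms_e
        out[f"F_{name}"] = F
        out[f"p_{name}"] = max(stats.f.sf(F, df_eff, err_df), P_FLOOR)
    return out, status


def fit_two_way_anova(experiment: ExpressionExperiment,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Fit the factorial model for every gene; return the ANOVA table.

    Columns: per effect F, raw p and BH-adjusted p (``adjBrix``,
    ``adjTissue``, ``adjInteraction``), per-cell means and counts, and a
    per-gene ``status``.  Genes with zero error variance or fewer than two
    usable factor levels are marked ``dropped_degenerate`` and carry NaN
    statistics.
    """
    brix_levels = experiment.brix_levels
    tissues = experiment.tissues
    a, b = len(brix_levels), len(tissues)
    if a < 2 or b < 2:
        raise ValueError("both factors need >= 2 levels")
    reps = experiment.design.groupby(["brix", "tissue"]).size()
    n = int(reps.iloc[0])
    if not (reps == n).all():
        raise ValueError("design must have equal replicate counts per cell")

    # reorder columns into (brix, tissue, replicate) blocks
    ordered = []
    for brix in brix_levels:
        for tissue in tissues:
            ordered.extend(experiment.condition_samples(brix, tissue))
    Y = experiment.values[ordered].to_numpy(dtype=float)
    genes = experiment.values.index
    Yc = Y.reshape(len(genes), a, b, n)

    complete = ~np.isnan(Y).any(axis=1)
    result = pd.DataFrame(index=genes)
    for eff in EFFECTS:
        result[f"F_{eff}"] = np.nan
        result[f"p_{eff}"] = np.nan
    result["status"] = STATUS_DROPPED

    if complete.any():
        stats_c = _classical_anova(Yc[complete], a, b, n)
        degen = stats_c["ss_total"] <= 0
        for eff in EFFECTS:
            F = stats_c[f"F_{eff}"].copy()
            p = stats_c[f"p_{eff}"].copy()
            F[degen] = np.nan
            p[degen] = np.nan
            result.loc[complete, f"F_{eff}"] = F
            result.loc[complete, f"p_{eff}"] = p
        status = np.where(degen, STATUS_DROPPED, STATUS_OK)
        result.loc[complete, "status"] = status

    brix_arr = experiment.design.loc[ordered, "brix"].to_numpy()
    tissue_arr = experiment.design.loc[ordered, "tissue"].to_numpy(dtype=str)
    for gi in np.flatnonzero(~complete):
        y = Y[gi]
        ok = ~np.isnan(y)
        yk, ba, ta = y[ok], brix_arr[ok], tissue_arr[ok]
        # a cell is retained only with >= 2 replicates; thinner cells are
        # unusable for the factorial error term
        cells = pd.DataFrame({"b": ba, "t": ta}).groupby(["b", "t"]).size()
        keep_cells = set(cells[cells >= 2].index)
        mask = np.array([(bb, tt) in keep_cells for bb, tt in zip(ba, ta)])
        if mask.sum() < 4:
            continue
        vals, status = _type2_anova_single(yk[mask], ba[mask], ta[mask])
        for key, v in vals.items():
            result.loc[genes[gi], key] = v
        result.loc[genes[gi], "status"] = status

    for eff, col in (("brix", "adjBrix"), ("tissue", "adjTissue"),
                     ("interaction", "adjInteraction")):
        result[col] = bh_adjust(result[f"p_{eff}"].to_numpy())

    means = experiment.condition_means()
    counts = experiment.values[ordered].notna().to_numpy().reshape(
        len(genes), a, b, n).sum(axis=3)
    for bi, brix in enumerate(brix_levels):
        for ti, tissue in enumerate(tissues):
            label = condition_label(brix, tissue)
            result[f"mean_{label}"] = means[label]
            result[f"n_{label}"] = counts[:, bi, ti]
    return result


def call_significant(anova_table: pd.DataFrame,
                     alpha: float = 0.05) -> dict[str, list[str]]:
    """Per-effect significant gene sets at strict ``adj p < alpha``."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    cols = {"brix": "adjBrix", "tissue": "adjTissue",
            "interaction": "adjInteraction"}
    return {eff: list(anova_table.index[anova_table[col] < alpha])
            for eff, col in cols.items()}


def compute_log2_contrast(experiment: ExpressionExperiment,
                          cell_a: tuple[float, str],
                          cell_b: tuple[float, str]) -> pd.Series:
    """Per-gene difference of condition means, in log2 units.

    On the log2 scale the difference of two condition means is the log of
    the linear fold ratio between the conditions.
    """
    means = experiment.condition_means()
    la, lb = condition_label(*cell_a), condition_label(*cell_b)
    for label in (la, lb):
        if label not in means.columns:
            raise KeyError(f"unknown condition cell {label}")
    contrast = means[la] - means[lb]
    contrast.name = f"{la}-{lb}"
    return contrast
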