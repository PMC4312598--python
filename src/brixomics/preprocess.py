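"""Normalization and replicate-set quality control.

Expression values are RMA-style log2 measures held in a gene x sample
matrix bound to a factorial (°Brix x tissue x replicate) sample design.
Quality control follows a coefficient-of-variation screen applied to each
replicate set (the six biological replicates of one gene in one condition):
sets whose CV exceeds a scrutiny threshold are inspected for values lying
more than a fixed number of standard deviations from the set mean; one or
two such values are removed, and sets that remain too dispersed after
removal are excluded outright.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING_TOKEN = "NA"

# Verdicts for a screened replicate set.
CLEAN = "clean"
SINGLE_REMOVED = "single_outlier_removed"
PAIR_REMOVED = "pair_removed"
SET_EXCLUDED = "set_excluded"


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionExperiment:
    """A log2 expression matrix bound to a factorial sample design.

    Parameters
    ----------
    values
        DataFrame of shape (n_genes, n_samples); ``NaN`` marks values
        excluded by quality control.
    design
        DataFrame indexed by sample id with columns ``brix`` (float),
        ``tissue`` (str) and ``replicate`` (int).
    """

    values: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        missing = set(self.values.columns) - set(self.design.index)
        if missing:
            raise ValueError(f"samples absent from design: {sorted(missing)[:5]}")
        self.design = self.design.loc[list(self.values.columns)]
        dup = self.design.groupby(["brix", "tissue", "replicate"]).size()
        if (dup > 1).any():
            raise ValueError("replicate indices not unique within a condition")

    # -- design helpers ----------------------------------------------------

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def brix_levels(self) -> list[float]:
        return sorted(self.design["brix"].unique())

    @property
    def tissues(self) -> list[str]:
        return sorted(self.design["tissue"].unique())

    @property
    def conditions(self) -> list[tuple[float, str]]:
        """All (brix, tissue) cells, brix-major then tissue order."""
        return [(b, t) for b in self.brix_levels for t in self.tissues]

    def condition_samples(self, brix: float, tissue: str) -> list[str]:
        mask = (self.design["brix"] == brix) & (self.design["tissue"] == tissue)
        sub = self.design[mask].sort_values("replicate")
        return list(sub.index)

    def condition_means(self) -> pd.DataFrame:
        """Gene x condition matrix of replicate means (NaN-aware)."""
        cols = {}
        for brix, tissue in self.conditions:
            ids = self.condition_samples(brix, tissue)
            cols[condition_label(brix, tissue)] = self.values[ids].mean(axis=1)
        return pd.DataFrame(cols, index=self.values.index)

    def copy(self) -> "ExpressionExperiment":
        return ExpressionExperiment(self.values.copy(), self.design.copy())

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, matrix_path: str | Path, design_path: str | Path) -> None:
        self.values.to_csv(matrix_path, sep="\t", na_rep=MISSING_TOKEN,
                           index_label="gene")
        sheet = self.design.reset_index(names="sample_id")
        sheet.to_csv(design_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, matrix_path: str | Path,
                 design_path: str | Path) -> "ExpressionExperiment":
        values = pd.read_csv(matrix_path, sep="\t", index_col=0,
                             na_values=[MISSING_TOKEN])
        design = pd.read_csv(design_path, sep="\t", index_col="sample_id")
        return cls(values, design)


def condition_label(brix: float, tissue: str) -> str:
    """Condition column name in the supplementary-table style, e.g. ``bx23.2Skin``."""
    return f"bx{brix:g}{tissue.capitalize()}"


@dataclass
class ReplicateSet:
    """The replicate values of one gene in one (brix, tissue) condition."""

    gene: str
    brix: float
    tissue: str
    values: np.ndarray
    replicates: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.replicates = np.asarray(self.replicates, dtype=int)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1))

    @property
    def cv(self) -> float:
        if self.mean <= 0:
            raise ValueError("CV undefined for non-positive mean")
        return self.sd / self.mean


@dataclass
class QCReport:
    """Bookkeeping of a replicate-set quality-control pass."""

    verdicts: pd.DataFrame          # gene, brix, tissue, verdict, n_removed
    removed: list[tuple[str, float, str, int]]  # (gene, brix, tissue, replicate)
    n_sets: int
    n_values_total: int
    n_single_removed: int = 0
    n_pair_removed_values: int = 0
    n_sets_excluded: int = 0
    n_values_retained: int = 0
    frac_sets_cv_above_scrutiny: float = 0.0
    mean_retained_cv: float = float("nan")
    thresholds: dict = field(default_factory=dict)

    @property
    def n_values_removed(self) -> int:
        return self.n_values_total - self.n_values_retained

    def conservation_holds(self) -> bool:
        """Retained + removed values must exactly account for the input."""
        per_set = self.n_values_total // self.n_sets if self.n_sets else 0
        accounted = (self.n_values_retained + self.n_single_removed
                     + self.n_pair_removed_values
                     + per_set * self.n_sets_excluded)
        return accounted == self.n_values_total and \
            len(self.removed) == self.n_values_removed

    def to_json(self, path: str | Path) -> None:
        payload = {
            "counts": {
                "n_sets": self.n_sets,
                "n_values_total": self.n_values_total,
                "n_single_removed": self.n_single_removed,
                "n_pair_removed_values": self.n_pair_removed_values,
                "n_sets_excluded": self.n_sets_excluded,
                "n_values_retained": self.n_values_retained,
            },
            "summary": {
                "frac_sets_cv_above_scrutiny": self.frac_sets_cv_above_scrutiny,
                "mean_retained_cv": self.mean_retained_cv,
            },
            "thresholds": self.thresholds,
            "removed": [list(r) for r in self.removed],
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    def to_tsv(self, path: str | Path) -> None:
        self.verdicts.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample column onto the common (row-mean) distribution.

    Each column is replaced, rank for rank, by the mean across columns of
    the column-sorted values.  Ties are broken by row order (stable sort),
    which makes the map idempotent.
    """
    if matrix.isna().any().any():
        raise ValueError("quantile normalization requires a complete matrix")
    if matrix.shape[1] < 2:
        warnings.warn("single-column matrix: quantile normalization is a no-op")
        return matrix.copy()
    x = matrix.to_numpy(dtype=float)
    order = np.argsort(x, axis=0, kind="stable")
    ref = np.mean(np.take_along_axis(x, order, axis=0), axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        out[order[:, j], j] = ref
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def median_polish_summarize(matrix: np.ndarray | pd.DataFrame,
                            max_iter: int = 10,
                            tol: float = 0.01,
                            return_fit: bool = False):
    """Summarize a probe x sample matrix into one value per sample.

    Tukey's median polish fits the additive model
    ``y_ij = overall + row_i + col_j + resid_ij`` by alternately sweeping
    medians out of rows and columns; the per-sample summary is
    ``overall + col_j``, robust to aberrant probe cells.

    Parameters
    ----------
    max_iter
        Maximum number of full (row + column) sweeps.
    tol
        Convergence tolerance on the relative change of the sum of
        absolute residuals.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if tol <= 0:
        raise ValueError("tol must be > 0")
    cols = None
    if isinstance(matrix, pd.DataFrame):
        cols = matrix.columns
        matrix = matrix.to_numpy(dtype=float)
    z = np.array(matrix, dtype=float)
    if z.ndim != 2 or z.size == 0:
        raise ValueError("matrix must be a non-empty 2-D array")
    nr, nc = z.shape
    overall = 0.0
    row = np.zeros(nr)
    col = np.zeros(nc)
    oldsum = 0.0
    for _ in range(max_iter):
        rmed = np.median(z, axis=1)
        z -= rmed[:, None]
        row += rmed
        delta = np.median(col)
        col -= delta
        overall += delta
        cmed = np.median(z, axis=0)
        z -= cmed[None, :]
        col += cmed
        delta = np.median(row)
        row -= delta
        overall += delta
        newsum = np.sum(np.abs(z))
        if newsum == 0 or abs(newsum - oldsum) < tol * newsum:
            break
        oldsum = newsum
    summary = overall + col
    if cols is not None:
        summary = pd.Series(summary, index=cols)
    if return_fit:
        return summary, {"overall": overall, "row": row, "col": col, "resid": z}
    return summary


# ---------------------------------------------------------------------------
# Replicate-set screening
# ---------------------------------------------------------------------------

def screen_replicate_set(values: Sequence[float] | ReplicateSet,
                         cv_scrutiny: float = 0.5,
                         sd_mult: float = 1.35,
                         cv_exclude: float = 0.85) -> tuple[str, list[int]]:
    """Screen one replicate set; return (verdict, removed indices).

    The set is scrutinized only when its CV (sd/mean, n-1 denominator)
    strictly exceeds ``cv_scrutiny``.  Values lying strictly more than
    ``sd_mult`` standard deviations from the full-set mean are flagged in a
    single pass: one flag removes that value, two flags remove both, three
    or more exclude the whole set.  If the survivors' CV still strictly
    exceeds ``cv_exclude`` the set is excluded outright.
    """
    if isinstance(values, ReplicateSet):
        values = values.values
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("replicate set must have at least 3 values")
    mean = x.mean()
    if mean <= 0:
        raise ValueError("CV undefined for non-positive mean")
    sd = x.std(ddof=1)
    cv = sd / mean
    if cv <= cv_scrutiny:
        return CLEAN, []
    flagged = np.flatnonzero(np.abs(x - mean) > sd_mult * sd)
    if flagged.size >= 3:
        return SET_EXCLUDED, list(range(x.size))
    removed = list(map(int, flagged))
    survivors = np.delete(x, flagged)
    smean = survivors.mean()
    scv = survivors.std(ddof=1) / smean if smean > 0 else np.inf
    if scv > cv_exclude:
        return SET_EXCLUDED, list(range(x.size))
    if flagged.size == 1:
        return SINGLE_REMOVED, removed
    if flagged.size == 2:
        return PAIR_REMOVED, removed
    return CLEAN, []


def apply_replicate_qc(experiment: ExpressionExperiment,
                       cv_scrutiny: float = 0.5,
                       sd_mult: float = 1.35,
                       cv_exclude: float = 0.85,
                       ) -> tuple[ExpressionExperiment, QCReport]:
    """Screen every replicate set and mask removed values as missing.

    Vectorized over genes within each condition.  Returns a copy of the
    experiment with removed values set to NaN, plus a :class:`QCReport`
    whose counts satisfy the conservation identity exactly.
    """
    values = experiment.values.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("input experiment already contains missing values")
    out = values.copy()
    genes = np.asarray(experiment.genes)
    verdict_rows = []
    removed: list[tuple[str, float, str, int]] = []
    n_single = 0
    n_pair_vals = 0
    n_excluded = 0
    n_scrutinized = 0
    n_sets = 0

    for brix, tissue in experiment.conditions:
        ids = experiment.condition_samples(brix, tissue)
        col_idx = [experiment.samples.index(s) for s in ids]
        reps = experiment.design.loc[ids, "replicate"].to_numpy()
        X = values[:, col_idx]                       # genes x n_reps
        n = X.shape[1]
        if n < 3:
            raise ValueError("replicate QC requires >= 3 replicates per set")
        n_sets += X.shape[0]
        mean = X.mean(axis=1)
        sd = X.std(axis=1, ddof=1)
        # sets at the detection floor (mean <= 0, i.e. all values clipped to
        # the scale minimum) have no defined CV and are left unscreened
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = np.where(mean > 0, sd / np.where(mean > 0, mean, 1.0), 0.0)
        scrut = cv > cv_scrutiny
        n_scrutinized += int(scrut.sum())
        flags = np.abs(X - mean[:, None]) > (sd_mult * sd)[:, None]
        flags[~scrut] = False
        nflag = flags.sum(axis=1)

        exclude = scrut & (nflag >= 3)
        cand = scrut & (nflag >= 1) & (nflag <= 2)
        # survivors' CV after removing flagged values
        surv = np.where(flags, np.nan, X)
        with np.errstate(invalid="ignore"):
            smean = np.nanmean(surv, axis=1)
            ssd = np.nanstd(surv, axis=1, ddof=1)
            scv = np.where(smean > 0, ssd / smean, np.inf)
        exclude |= cand & (scv > cv_exclude)
        # zero-flag scrutinized sets: nothing removable, exclude if still wild
        none_flagged = scrut & (nflag == 0)
        exclude |= none_flagged & (cv > cv_exclude)

        single = cand & (nflag == 1) & ~exclude
        pair = cand & (nflag == 2) & ~exclude

        for gi in np.flatnonzero(exclude):
            out[gi, col_idx] = np.nan
            removed.extend((genes[gi], brix, tissue, int(r)) for r in reps)
            verdict_rows.append((genes[gi], brix, tissue, SET_EXCLUDED, n))
        n_excluded += int(exclude.sum())
        for gi in np.flatnonzero(single | pair):
            rs = np.flatnonzero(flags[gi])
            for r in rs:
                out[gi, col_idx[r]] = np.nan
                removed.append((genes[gi], brix, tissue, int(reps[r])))
            verdict = SINGLE_REMOVED if single[gi] else PAIR_REMOVED
            verdict_rows.append((genes[gi], brix, tissue, verdict, len(rs)))
        n_single += int(single.sum())
        n_pair_vals += 2 * int(pair.sum())
        for gi in np.flatnonzero(~exclude & ~single & ~pair):
            verdict_rows.append((genes[gi], brix, tissue, CLEAN, 0))

    filtered = ExpressionExperiment(
        pd.DataFrame(out, index=experiment.values.index,
                     columns=experiment.values.columns),
        experiment.design.copy())

    # retained-set CV summary (NaN-aware, sets not fully excluded)
    retained_cvs = []
    for brix, tissue in experiment.conditions:
        ids = experiment.condition_samples(brix, tissue)
        X = filtered.values[ids].to_numpy()
        ok = ~np.isnan(X)
        keep = ok.sum(axis=1) >= 2
        with np.errstate(invalid="ignore"):
            m = np.nanmean(X[keep], axis=1)
            s = np.nanstd(X[keep], axis=1, ddof=1)
        retained_cvs.append(s[m > 0] / m[m > 0])
    all_cv = np.concatenate(retained_cvs) if retained_cvs else np.array([])

    report = QCReport(
        verdicts=pd.DataFrame(
            verdict_rows,
            columns=["gene", "brix", "tissue", "verdict", "n_removed"]),
        removed=removed,
        n_sets=n_sets,
        n_values_total=int(values.size),
        n_single_removed=n_single,
        n_pair_removed_values=n_pair_vals,
        n_sets_excluded=n_excluded,
        n_values_retained=int(values.size) - len(removed),
        frac_sets_cv_above_scrutiny=n_scrutinized / n_sets if n_sets else 0.0,
        mean_retained_cv=float(np.mean(all_cv)) if all_cv.size else float("nan"),
        thresholds={"cv_scrutiny": cv_scrutiny, "sd_mult": sd_mult,
                    "cv_exclude": cv_exclude},
    )
    return filtered, report
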