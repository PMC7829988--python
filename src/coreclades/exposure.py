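"""Negative-binomial exposure-sensitivity models for core clades.

Each study carries its own exposure arms (plus a ``control`` arm), so a
separate log-link negative-binomial regression is fitted per (study, clade):
clade abundance in a sample as a function of that sample's exposure
condition, control as the base level.  The per-level Wald coefficient is
the log fold change in expected clade abundance relative to control; levels
with BH-adjusted p below the threshold (default 0.1) mark the clade as
sensitive to that exposure.

Fits use maximum likelihood for both the coefficients and the NB dispersion
(NB2 parameterisation), matching the glm.nb contract.  Because the inputs
are agglomerated counts from rarefied samples (equal totals), no offset is
used by default; ``use_offset`` adds a log-total offset for raw counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.discrete.discrete_model import NegativeBinomial
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning, HessianInversionWarning

__all__ = [
    "ExposureDesign",
    "NbFit",
    "SensitivityRecord",
    "fit_nb_glm",
    "sensitivity_scan",
    "summarize_sensitivity",
]

CONTROL_LEVEL = "control"
DEFAULT_FDR = 0.1
MAX_ZERO_FRACTION = 0.95


@dataclass
class ExposureDesign:
    """Per-study design: sample ids and their exposure levels.

    ``levels`` maps each sample id to its exposure label; the base level is
    ``control``.  Each level must have at least 2 samples.
    """

    study: str
    levels: pd.Series  # index: sample ids, values: exposure labels

    def __post_init__(self) -> None:
        counts = self.levels.value_counts()
        if CONTROL_LEVEL not in counts or counts[CONTROL_LEVEL] < 2:
            raise ValueError(
                f"study {self.study!r}: base level '{CONTROL_LEVEL}' needs >=2 samples"
            )
        small = counts[counts < 2]
        if len(small):
            raise ValueError(
                f"study {self.study!r}: levels with <2 samples: {list(small.index)}"
            )

    @property
    def exposure_levels(self) -> list[str]:
        return sorted(set(self.levels) - {CONTROL_LEVEL})

    @property
    def sample_ids(self) -> list[str]:
        return list(self.levels.index)


@dataclass
class NbFit:
    """One NB regression: per-exposure-level effects plus dispersion."""

    coef: dict[str, tuple[float, float, float]]  # level -> (beta, se, p)
    dispersion: float  # NB size parameter (1/alpha); inf in the Poisson limit
    intercept: float
    converged: bool
    status: str = "ok"  # ok | degenerate | insufficient_signal | failed


@dataclass
class SensitivityRecord:
    study: str
    clade_id: str
    exposure_level: str
    beta: float
    se: float
    p: float
    q: float = np.nan
    sensitive: bool = False
    dispersion: float = np.nan
    status: str = "ok"


def _design_matrix(levels: pd.Series) -> tuple[np.ndarray, list[str]]:
    """Intercept + one dummy per non-control level (control = base)."""
    exp_levels = sorted(set(levels) - {CONTROL_LEVEL})
    X = np.ones((len(levels), 1 + len(exp_levels)))
    for j, lev in enumerate(exp_levels):
        X[:, 1 + j] = (levels == lev).to_numpy(dtype=float)
    return X, exp_levels


def fit_nb_glm(
    y: np.ndarray | pd.Series,
    design: ExposureDesign,
    use_offset: bool = False,
    totals: np.ndarray | None = None,
    max_zero_fraction: float = MAX_ZERO_FRACTION,
) -> NbFit:
    """ML negative-binomial regression of counts on exposure condition.

    Returns per-level (beta, se, Wald p) against the control base level and
    the estimated NB size parameter.  All-zero responses and responses that
    are almost entirely zero are not fitted (status ``degenerate`` /
    ``insufficient_signal``): dispersion estimation is unstable there.
    Non-convergence is flagged and p-values set to NaN.
    """
    if isinstance(y, pd.Series):
        y = y.loc[design.levels.index].to_numpy()
    y = np.asarray(y)
    if len(y) != len(design.levels):
        raise ValueError("y and design have different lengths")
    if np.any(y < 0) or not np.allclose(y, np.round(y)):
        raise ValueError("y must be non-negative integer counts")
    X, exp_levels = _design_matrix(design.levels)
    if not exp_levels:
        raise ValueError(f"study {design.study!r} has no non-control level")

    nan_coef = {lev: (np.nan, np.nan, np.nan) for lev in exp_levels}
    if (y == 0).all():
        return NbFit(nan_coef, np.nan, np.nan, False, status="degenerate")
    if (y == 0).mean() > max_zero_fraction:
        return NbFit(nan_coef, np.nan, np.nan, False, status="insufficient_signal")

    offset = None
    if use_offset:
        if totals is None:
            raise ValueError("use_offset requires per-sample totals")
        offset = np.log(np.asarray(totals, dtype=float))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        warnings.simplefilter("ignore", category=HessianInversionWarning)
        warnings.simplefilter("ignore", category=RuntimeWarning)
        try:
            model = NegativeBinomial(y, X, loglike_method="nb2", offset=offset)
            res = model.fit(disp=0, maxiter=200, method="bfgs", gtol=1e-7)
            converged = bool(res.mle_retvals.get("converged", False))
            params = np.asarray(res.params)
            bse = np.asarray(res.bse)
            pvals = np.asarray(res.pvalues)
        except Exception:
            return NbFit(nan_coef, np.nan, np.nan, False, status="failed")

    alpha = float(params[-1])
    size = np.inf if alpha <= 1e-10 else 1.0 / alpha
    coef: dict[str, tuple[float, float, float]] = {}
    for j, lev in enumerate(exp_levels):
        b, se, p = float(params[1 + j]), float(bse[1 + j]), float(pvals[1 + j])
        if not converged:
            p = np.nan
        coef[lev] = (b, se, p)
    status = "ok" if converged else "not_converged"
    return NbFit(coef, size, float(params[0]), converged, status=status)


def sensitivity_scan(
    clade_matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    fdr: float = DEFAULT_FDR,
    fdr_scope: str = "study",
) -> list[SensitivityRecord]:
    """Fit one NB model per (study, clade); flag levels with q < ``fdr``.

    ``clade_matrix`` is clades x samples (typically restricted to core
    clades); ``metadata`` is indexed by sample id with ``study`` and
    ``exposure`` columns, ``exposure == "control"`` marking the base arm.
    FDR correction (BH) is applied within each study across all clade x
    exposure-level tests, or globally with ``fdr_scope="global"``.
    Studies without a usable control arm are skipped with a warning.
    """
    if fdr_scope not in {"study", "global"}:
        raise ValueError("fdr_scope must be 'study' or 'global'")
    records: list[SensitivityRecord] = []
    samples = [s for s in clade_matrix.columns if s in metadata.index]
    meta = metadata.loc[samples]
    for study, sub in meta.groupby("study", sort=True):
        levels = sub["exposure"]
        n_control = int((levels == CONTROL_LEVEL).sum())
        n_exposed_levels = len(set(levels) - {CONTROL_LEVEL})
        if n_control < 2 or n_exposed_levels == 0:
            warnings.warn(
                f"study {study!r}: no usable control/exposure arms; skipped"
            )
            continue
        # drop levels with a single sample (cannot be modelled)
        ok_levels = levels.value_counts()
        keep = levels.isin(ok_levels[ok_levels >= 2].index)
        design = ExposureDesign(study=str(study), levels=levels[keep])
        ymat = clade_matrix[design.sample_ids]
        study_records: list[SensitivityRecord] = []
        for clade_id, yrow in ymat.iterrows():
            fit = fit_nb_glm(yrow.to_numpy(), design)
            for lev, (b, se, p) in fit.coef.items():
                study_records.append(
                    SensitivityRecord(
                        study=str(study),
                        clade_id=str(clade_id),
                        exposure_level=lev,
                        beta=b,
                        se=se,
                        p=p,
                        dispersion=fit.dispersion,
                        status=fit.status,
                    )
                )
        if fdr_scope == "study":
            _apply_fdr(study_records, fdr)
        records.extend(study_records)
    if fdr_scope == "global":
        _apply_fdr(records, fdr)
    return records


def _apply_fdr(records: list[SensitivityRecord], fdr: float) -> None:
    testable = [r for r in records if np.isfinite(r.p)]
    if not testable:
        return
    _, qs, _, _ = multipletests([r.p for r in testable], alpha=fdr, method="fdr_bh")
    for r, q in zip(testable, qs):
        r.q = float(q)
        r.sensitive = bool(q < fdr)


def records_to_frame(records: list[SensitivityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "study": r.study,
                "clade_id": r.clade_id,
                "exposure_level": r.exposure_level,
                "beta": r.beta,
                "se": r.se,
                "p": r.p,
                "q": r.q,
                "sensitive": r.sensitive,
                "dispersion": r.dispersion,
                "status": r.status,
            }
            for r in records
        ]
    )


@dataclass
class SensitivitySummary:
    per_clade: pd.DataFrame  # clade_id -> n_sensitive_exposures
    per_exposure: pd.DataFrame  # (study, exposure_level) -> n_sensitive_clades
    robust_clades: set[str] = field(default_factory=set)
    coef_matrix: pd.DataFrame | None = None  # clades x (study, level) betas


def summarize_sensitivity(records: list[SensitivityRecord]) -> SensitivitySummary:
    """Count sensitive exposures per clade and sensitive clades per exposure.

    An "exposure" is a (study, exposure_level) pair: the same chemical used
    in two studies counts as two exposures, since arms are modelled per
    study.  Clades sensitive to nothing form the robust set.
    """
    df = records_to_frame(records)
    if df.empty:
        return SensitivitySummary(
            per_clade=pd.DataFrame(columns=["n_sensitive_exposures"]),
            per_exposure=pd.DataFrame(columns=["n_sensitive_clades"]),
        )
    clades = sorted(df["clade_id"].unique())
    sens = df[df["sensitive"]]
    uniq = sens[["clade_id", "study", "exposure_level"]].drop_duplicates()
    per_clade = (
        uniq.groupby("clade_id")
        .size()
        .reindex(clades, fill_value=0)
        .rename("n_sensitive_exposures")
        .to_frame()
    )
    per_exposure = (
        sens.groupby(["study", "exposure_level"])["clade_id"]
        .nunique()
        .rename("n_sensitive_clades")
        .to_frame()
    )
    all_pairs = df[["study", "exposure_level"]].drop_duplicates()
    per_exposure = per_exposure.reindex(
        pd.MultiIndex.from_frame(all_pairs), fill_value=0
    )
    robust = set(per_clade.index[per_clade["n_sensitive_exposures"] == 0])
    coef = df.pivot_table(
        index="clade_id",
        columns=["study", "exposure_level"],
        values="beta",
        aggfunc="first",
    )
    return SensitivitySummary(
        per_clade=per_clade,
        per_exposure=per_exposure,
        robust_clades=robust,
        coef_matrix=coef,
    )
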