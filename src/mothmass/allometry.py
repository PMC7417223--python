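"""Allometric mixed-model fitting for forewing length -> dry body mass.

The model is a linear mixed model on the natural-log response scale with a
species random intercept and family-by-length fixed effects:

    ln(M_isf) = (b0 + b0_f) + (b1 + b1_f) * t(L_isf) + u_s + e_isf
    u_s ~ N(0, sigma_s^2),  e ~ N(0, sigma_e^2)

where ``t`` is the predictor transform of the chosen structure: the raw length
(``linear``), its natural log (``loglog``), or a broken-stick basis with a
single shared breakpoint (``segmented``). Families are treatment-coded against
the pooled "other" group so that retained families' coefficients read directly
as refinements added to the reference parameters.

All fits use maximum likelihood (not REML) so that BIC comparisons and
likelihood-ratio tests across fixed-effect structures are valid.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from statsmodels.regression.mixed_linear_model import MixedLM

from .params import AllometricParameters, FamilyGrouping

logger = logging.getLogger(__name__)

__all__ = [
    "STRUCTURES",
    "ConvergenceError",
    "MixedModelFit",
    "LRTResult",
    "MothMassRegressor",
    "group_families",
    "fit_mixed_allometry",
    "select_structure",
    "lrt_family_interaction",
    "marginal_r2",
    "extract_parameters",
]

STRUCTURES = ("linear", "loglog", "segmented")

REQUIRED_COLUMNS = ("species", "family", "forewing_length_mm", "dry_mass_mg")


class ConvergenceError(RuntimeError):
    """Mixed-model optimizer failed to converge; carries diagnostics."""


@dataclass
class LRTResult:
    """Likelihood-ratio test between two nested ML fits."""

    chi_square: float
    df: int
    p_value: float


@dataclass
class MixedModelFit:
    """A converged mixed-model fit plus everything needed to reuse it.

    ``fixed_effects`` maps coefficient name -> (estimate, standard error), in
    design-matrix order. ``bic`` counts fixed effects, both variance
    components, and (for the segmented structure) the breakpoint.
    """

    structure: str
    fixed_effects: dict[str, tuple[float, float]]
    random_intercept_variance: float
    residual_variance: float
    log_likelihood: float
    bic: float
    n_obs: int
    n_species: int
    n_groups: int
    grouping: FamilyGrouping
    reference: str
    levels: list[str]
    breakpoint_mm: float | None = None
    converged: bool = True
    obs_fingerprint: str = ""
    marginal_r2_: float | None = field(default=None, repr=False)

    @property
    def n_parameters(self) -> int:
        k = len(self.fixed_effects) + 2  # + random-intercept and residual variances
        if self.structure == "segmented":
            k += 1  # the estimated breakpoint
        return k

    def fixed_prediction(self, records: pd.DataFrame) -> np.ndarray:
        """Fixed-effects-only prediction of ln(mass) for new records."""
        groups = records["family"].map(self.grouping.group_of).to_numpy(dtype=object)
        X, names = _design_matrix(
            records["forewing_length_mm"].to_numpy(dtype=float),
            groups,
            self.structure,
            self.levels,
            self.breakpoint_mm,
        )
        beta = np.array([self.fixed_effects[n][0] for n in names])
        return X @ beta


# --------------------------------------------------------------------------
# grouping


def group_families(
    records: pd.DataFrame, threshold: int = 5, other_label: str = "other"
) -> FamilyGrouping:
    """Derive the family -> group mapping from training records.

    Families represented by at least ``threshold`` distinct species keep their
    own label; all others pool into ``other_label``.
    """
    if len(records) == 0:
        raise ValueError("no records: cannot derive a family grouping from empty data")
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    counts = records.groupby("family")["species"].nunique()
    mapping = {
        fam: (fam if n >= threshold else other_label) for fam, n in counts.items()
    }
    return FamilyGrouping(mapping=mapping, threshold=threshold, other_label=other_label)


# --------------------------------------------------------------------------
# design matrices


def _design_matrix(lengths, groups, structure, levels, breakpoint_mm=None):
    """Treatment-coded design matrix; ``levels[0]`` is the reference level."""
    lengths = np.asarray(lengths, dtype=float)
    if structure == "loglog":
        bases = {"ln_length": np.log(lengths)}
    elif structure == "linear":
        bases = {"length": lengths}
    elif structure == "segmented":
        if breakpoint_mm is None:
            raise ValueError("segmented structure needs a breakpoint")
        bases = {
            "length": lengths,
            "hinge": np.maximum(lengths - breakpoint_mm, 0.0),
        }
    else:
        raise ValueError(f"unknown structure {structure!r}")

    cols = [np.ones_like(lengths)]
    names = ["intercept"]
    for bname, b in bases.items():
        cols.append(b)
        names.append(bname)
    for lev in levels[1:]:
        d = (groups == lev).astype(float)
        cols.append(d)
        names.append(f"family[{lev}]")
        for bname, b in bases.items():
            cols.append(d * b)
            names.append(f"family[{lev}]:{bname}")
    return np.column_stack(cols), names


def _fingerprint(records: pd.DataFrame) -> str:
    key = records[["species", "forewing_length_mm", "dry_mass_mg"]].copy()
    key = key.sort_values(list(key.columns)).round(6)
    return hashlib.sha1(key.to_csv(index=False).encode()).hexdigest()


def _validate_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"records missing required columns: {missing}")
    if len(records) == 0:
        raise ValueError("no records to fit")
    records = records.dropna(subset=["dry_mass_mg"])
    if (records["forewing_length_mm"] <= 0).any():
        raise ValueError("forewing_length_mm must be positive")
    if (records["dry_mass_mg"] <= 0).any():
        raise ValueError("dry_mass_mg must be positive")
    fam_per_species = records.groupby("species")["family"].nunique()
    bad = fam_per_species[fam_per_species > 1]
    if len(bad):
        raise ValueError(
            f"species mapped to multiple families: {list(bad.index[:5])}"
        )
    return records


def _fit_ml(endog, exog, species, names) -> "MixedLM":
    """ML fit with a fallback chain of optimizers; raises ConvergenceError.

    A result only counts as converged if its log-likelihood and variance
    components are finite and sane; optimizers occasionally report success
    at a degenerate point (residual variance collapsing to zero), in which
    case the best sane candidate across optimizers is used instead.
    """
    model = MixedLM(endog, exog, groups=species)
    last = None
    for method in (["lbfgs"], ["bfgs"], ["powell"], ["cg", "nm"]):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = model.fit(reml=False, method=method, maxiter=2000)
            except (np.linalg.LinAlgError, ValueError) as exc:  # pragma: no cover
                last = exc
                continue
        sane = (
            np.isfinite(res.llf)
            and res.scale > 0.0
            and np.all(np.isfinite(res.fe_params))
            and np.isfinite(np.asarray(res.cov_re)).all()
        )
        if res.converged and sane:
            return res
        last = (
            f"optimizer {method} reported non-convergence"
            if not res.converged
            else "degenerate optimum (non-finite likelihood or zero variance)"
        )
    raise ConvergenceError(
        f"mixed model did not converge (n={len(endog)}, p={exog.shape[1]}): {last}"
    )


def _result_to_fit(res, structure, grouping, reference, levels, names, records,
                   breakpoint_mm=None) -> MixedModelFit:
    sigma_s2 = float(np.asarray(res.cov_re).ravel()[0])
    if sigma_s2 <= 1e-10:
        warnings.warn(
            "species random-intercept variance estimated at ~0 (singular fit)",
            stacklevel=3,
        )
    fe = {
        name: (float(est), float(se))
        for name, est, se in zip(names, res.fe_params, res.bse_fe)
    }
    k = len(fe) + 2 + (1 if structure == "segmented" else 0)
    n = len(records)
    fit = MixedModelFit(
        structure=structure,
        fixed_effects=fe,
        random_intercept_variance=sigma_s2,
        residual_variance=float(res.scale),
        log_likelihood=float(res.llf),
        bic=float(-2.0 * res.llf + k * np.log(n)),
        n_obs=n,
        n_species=int(records["species"].nunique()),
        n_groups=len(levels),
        grouping=grouping,
        reference=reference,
        levels=list(levels),
        breakpoint_mm=breakpoint_mm,
        converged=bool(res.converged),
        obs_fingerprint=_fingerprint(records),
    )
    var_fixed = float(np.var(fit.fixed_prediction(records), ddof=1))
    denom = var_fixed + sigma_s2 + fit.residual_variance
    fit.marginal_r2_ = var_fixed / denom if denom > 0 else 0.0
    return fit


def _candidate_breakpoints(lengths: np.ndarray, trim: int = 3) -> np.ndarray:
    uniq = np.unique(lengths)
    if len(uniq) <= 2 * trim + 1:
        return uniq[1:-1] if len(uniq) > 2 else uniq
    return uniq[trim:-trim]


# --------------------------------------------------------------------------
# the estimator


class MothMassRegressor(BaseEstimator, RegressorMixin):
    """Predict moth dry body mass (mg) from forewing length and family.

    A scikit-learn-style estimator around the species-random-intercept mixed
    model. ``fit`` expects a DataFrame with columns ``species``, ``family``,
    ``forewing_length_mm`` and (unless ``y`` is given) ``dry_mass_mg``;
    ``predict`` needs only ``forewing_length_mm`` and ``family`` and returns
    masses in mg from the fixed effects alone.

    Parameters
    ----------
    structure : {"loglog", "linear", "segmented"}
        Predictor transform; the response is always ln(mass).
    family_threshold : int
        Minimum distinct species for a family to keep its own parameters.
    other_label : str
        Label of the pooled reference group.
    reference : str or None
        Treatment-coding reference level; defaults to ``other_label`` when
        that group is present in the data.
    grouping : FamilyGrouping or None
        Pre-computed grouping; overrides threshold-based derivation.
    """

    def __init__(
        self,
        structure: str = "loglog",
        family_threshold: int = 5,
        other_label: str = "other",
        reference: str | None = None,
        grouping: FamilyGrouping | None = None,
    ):
        self.structure = structure
        self.family_threshold = family_threshold
        self.other_label = other_label
        self.reference = reference
        self.grouping = grouping

    # -- fitting ---------------------------------------------------------

    def fit(self, X: pd.DataFrame, y=None) -> "MothMassRegressor":
        if self.structure not in STRUCTURES:
            raise ValueError(f"structure must be one of {STRUCTURES}")
        records = X.copy()
        if y is not None:
            records["dry_mass_mg"] = np.asarray(y, dtype=float)
        records = _validate_records(records)

        grouping = self.grouping or group_families(
            records, threshold=self.family_threshold, other_label=self.other_label
        )
        groups = records["family"].map(grouping.group_of).to_numpy(dtype=object)
        present = sorted(set(groups))
        reference = self.reference
        if reference is None:
            reference = (
                grouping.other_label if grouping.other_label in present else present[0]
            )
        if reference not in present:
            raise ValueError(f"reference level {reference!r} not present in data")
        levels = [reference] + [g for g in present if g != reference]

        endog = np.log(records["dry_mass_mg"].to_numpy(dtype=float))
        lengths = records["forewing_length_mm"].to_numpy(dtype=float)
        species = records["species"].to_numpy(dtype=object)

        if self.structure == "segmented":
            res, names, psi = self._fit_segmented(endog, lengths, groups, species, levels)
        else:
            Xd, names = _design_matrix(lengths, groups, self.structure, levels)
            res = _fit_ml(endog, Xd, species, names)
            psi = None

        self.fit_ = _result_to_fit(
            res, self.structure, grouping, reference, levels, names, records,
            breakpoint_mm=psi,
        )
        self.grouping_ = grouping
        self.levels_ = levels
        self.n_features_in_ = len(REQUIRED_COLUMNS)
        if self.structure == "loglog":
            self.params_ = extract_parameters(self.fit_)
        return self

    def _fit_segmented(self, endog, lengths, groups, species, levels):
        """Profile-likelihood grid search for a single shared breakpoint."""
        best = None
        for psi in _candidate_breakpoints(lengths):
            Xd, names = _design_matrix(lengths, groups, "segmented", levels, psi)
            try:
                res = _fit_ml(endog, Xd, species, names)
            except ConvergenceError:
                continue
            if best is None or res.llf > best[0].llf:
                best = (res, names, float(psi))
        if best is None:
            raise ConvergenceError("segmented fit failed at every candidate breakpoint")
        return best

    # -- prediction --------------------------------------------------------

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Predicted dry mass in mg (fixed effects only)."""
        if not hasattr(self, "fit_"):
            raise RuntimeError("estimator is not fitted")
        return np.exp(self.fit_.fixed_prediction(X))


# --------------------------------------------------------------------------
# functional surface


def fit_mixed_allometry(
    records: pd.DataFrame,
    structure: str = "loglog",
    grouping: FamilyGrouping | None = None,
    reference: str | None = None,
) -> MixedModelFit:
    """Fit one candidate structure by maximum likelihood; see MothMassRegressor."""
    est = MothMassRegressor(structure=structure, grouping=grouping, reference=reference)
    return est.fit(records).fit_


def select_structure(fits: list[MixedModelFit]) -> MixedModelFit:
    """Pick the minimum-BIC fit; ties broken toward fewer parameters."""
    if not fits:
        raise ValueError("no fits supplied")
    prints = {f.obs_fingerprint for f in fits}
    if len(prints) > 1:
        raise ValueError("fits were made on differing record sets; BIC not comparable")
    return min(fits, key=lambda f: (f.bic, f.n_parameters))


def lrt_family_interaction(
    records: pd.DataFrame,
    grouping: FamilyGrouping | None = None,
    structure: str = "loglog",
) -> LRTResult:
    """Likelihood-ratio test of the family-by-length interaction.

    The reduced model drops only the interaction coefficients (family main
    effects stay). With a single group the two models coincide and the test
    is degenerate (chi^2 = 0, df = 0, p = 1).
    """
    records = _validate_records(records)
    grouping = grouping or group_families(records)
    full = fit_mixed_allometry(records, structure=structure, grouping=grouping)
    n_interactions = sum(
        1 for name in full.fixed_effects if name.startswith("family[") and ":" in name
    )
    if n_interactions == 0:
        return LRTResult(chi_square=0.0, df=0, p_value=1.0)

    groups = records["family"].map(grouping.group_of).to_numpy(dtype=object)
    Xfull, names_full = _design_matrix(
        records["forewing_length_mm"].to_numpy(dtype=float),
        groups,
        structure,
        full.levels,
        full.breakpoint_mm,
    )
    keep = [i for i, n in enumerate(names_full) if not (n.startswith("family[") and ":" in n)]
    Xred = Xfull[:, keep]
    names_red = [names_full[i] for i in keep]
    endog = np.log(records["dry_mass_mg"].to_numpy(dtype=float))
    res_red = _fit_ml(endog, Xred, records["species"].to_numpy(dtype=object), names_red)

    chi2 = 2.0 * (full.log_likelihood - float(res_red.llf))
    chi2 = max(chi2, 0.0)
    return LRTResult(
        chi_square=chi2,
        df=n_interactions,
        p_value=float(stats.chi2.sf(chi2, n_interactions)),
    )


def marginal_r2(fit: MixedModelFit, records: pd.DataFrame) -> float:
    """Variance explained by fixed effects alone, on the ln response scale.

    var(fixed predictions) / (var(fixed predictions) + sigma_s^2 + sigma_e^2).
    """
    var_fixed = float(np.var(fit.fixed_prediction(records), ddof=1))
    denom = var_fixed + fit.random_intercept_variance + fit.residual_variance
    return var_fixed / denom if denom > 0 else 0.0


def extract_parameters(
    fit: MixedModelFit, grouping: FamilyGrouping | None = None
) -> AllometricParameters:
    """Turn a loglog fit's fixed effects into prediction parameters.

    Reference slope/intercept are the effective values of the pooled "other"
    group; each retained family's adjustments are differences from those, so
    predictions from the result equal the fit's fixed-effect predictions
    regardless of which level was the coding reference.
    """
    if fit.structure != "loglog":
        raise ValueError(
            "prediction parameters are defined only for the loglog structure"
        )
    grouping = grouping or fit.grouping
    fe = fit.fixed_effects
    base_int, base_slope = fe["intercept"][0], fe["ln_length"][0]
    effective = {}
    for lev in fit.levels:
        di = fe.get(f"family[{lev}]", (0.0, 0.0))[0]
        ds = fe.get(f"family[{lev}]:ln_length", (0.0, 0.0))[0]
        effective[lev] = (base_slope + ds, base_int + di)

    ref_level = (
        grouping.other_label if grouping.other_label in effective else fit.reference
    )
    ref_slope, ref_int = effective[ref_level]
    adjustments = {
        lev: (s - ref_slope, i - ref_int)
        for lev, (s, i) in effective.items()
        if lev != ref_level
    }
    for lev, (s, _) in effective.items():
        if s <= 0:
            warnings.warn(f"non-positive effective slope for group {lev!r}")
    return AllometricParameters(
        reference_slope=ref_slope,
        reference_intercept=ref_int,
        family_adjustments=adjustments,
        grouping=grouping,
        provenance={
            "n_obs": fit.n_obs,
            "n_species": fit.n_species,
            "n_groups": fit.n_groups,
            "log_likelihood": fit.log_likelihood,
            "bic": fit.bic,
            "marginal_r2": fit.marginal_r2_,
            "converged": fit.converged,
        },
    )
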