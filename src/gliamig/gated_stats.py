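"""Gated inference for the explant migration assays.

Log-scale linear mixed models (litter and slice-within-litter random
intercepts) with treatment fixed effects; a family-level F gate is tested
first, and member-level Wald comparisons against control run only behind
open gates. Per-slice migrated-cell counts are analyzed the same way on
log(count + 1) with litter as the sole random effect. Also includes the
paired-t power calculator used for the detectable-effect statements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import migration
from .errors import ComputationError, ParameterError
from .lmm import LMMResult, fit_lmm, satterthwaite_df_multi, satterthwaite_df_scalar

DEFAULT_ALPHA = 0.05

DEFAULT_FAMILIES = {
    "NMDAR": ("D-AP5", "MK801"),
    "AMPAR/KAR": ("CNQX", "NBQX"),
    "combinations": ("MK801+NBQX", "D-AP5+CNQX"),
    "transporter": ("TFB-TBOA",),
}


@dataclass
class TreatmentFamilies:
    """Mapping family name -> member treatment labels; control is in no family."""

    families: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_FAMILIES.items()}
    )

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for fam, members in self.families.items():
            if not members:
                raise ParameterError(f"family {fam!r} has no members")
            for m in members:
                if m == "control":
                    raise ParameterError("'control' cannot belong to a family")
                if m in seen:
                    raise ParameterError(
                        f"treatment {m!r} appears in both {seen[m]!r} and {fam!r}"
                    )
                seen[m] = fam

    def validate_partition(self, treatments) -> None:
        """Check the families partition the non-control treatments present."""
        noncontrol = {t for t in treatments if t != "control"}
        members = {m for ms in self.families.values() for m in ms}
        extra = noncontrol - members
        if extra:
            raise ParameterError(f"treatments not assigned to any family: {sorted(extra)}")


OUTCOMES = ("net", "lateral", "radial", "cc_to_ctx")


@dataclass
class FittedModel:
    """A fitted treatment model plus the bookkeeping the gate needs."""

    lmm: LMMResult
    outcome: str
    treatments: tuple[str, ...]  # non-control levels, in design order
    n_obs: int

    def coefficient(self, treatment: str) -> tuple[float, float]:
        """(log-scale estimate, standard error) for one treatment vs control."""
        name = f"treatment[{treatment}]"
        j = list(self.lmm.beta.index).index(name)
        return float(self.lmm.beta.iloc[j]), float(np.sqrt(self.lmm.cov_beta[j, j]))

    def ratio(self, treatment: str) -> float:
        """Back-transformed treated/control ratio."""
        est, _ = self.coefficient(treatment)
        return float(np.exp(est))

    def ratio_ci(self, treatment: str, level: float = 0.95) -> tuple[float, float]:
        est, se = self.coefficient(treatment)
        df = satterthwaite_df_scalar(self.lmm, self._contrast(treatment))
        if df is None:
            df = self.lmm.df_containment
        half = stats.t.ppf(0.5 + level / 2, df) * se
        return float(np.exp(est - half)), float(np.exp(est + half))

    def _contrast(self, treatment: str) -> np.ndarray:
        name = f"treatment[{treatment}]"
        l = np.zeros(len(self.lmm.beta))
        l[list(self.lmm.beta.index).index(name)] = 1.0
        return l

    def summary(self) -> dict:
        out = {
            "outcome": self.outcome,
            "n_obs": self.n_obs,
            "n_litters": self.lmm.n_litters,
            "n_slices": self.lmm.n_slices,
            "sigma2_resid": self.lmm.sigma2_resid,
            "sigma2_litter": self.lmm.sigma2_litter,
            "sigma2_slice": self.lmm.sigma2_slice,
            "converged": self.lmm.converged,
            "warnings": list(self.lmm.warnings),
            "coefficients": {},
        }
        for tr in self.treatments:
            est, se = self.coefficient(tr)
            out["coefficients"][tr] = {"log_effect": est, "se": se, "ratio": float(np.exp(est))}
        return out


def _design_matrix(data: pd.DataFrame) -> tuple[np.ndarray, list[str], tuple[str, ...]]:
    levels = [t for t in pd.unique(data["treatment"]) if t != "control"]
    levels = sorted(levels)
    X = np.ones((len(data), 1 + len(levels)))
    names = ["Intercept"]
    for j, tr in enumerate(levels, start=1):
        X[:, j] = (data["treatment"] == tr).to_numpy(float)
        names.append(f"treatment[{tr}]")
    return X, names, tuple(levels)


def fit_migration_model(records: pd.DataFrame, outcome: str) -> FittedModel:
    """Log-scale mixed model of one migration outcome vs treatment.

    Random intercepts for litter and slice nested within litter; rows with
    missing outcome (e.g. cells not on the cortex side for cc_to_ctx) are
    dropped. Outcome values must be strictly positive.
    """
    if outcome not in OUTCOMES:
        raise ParameterError(f"outcome must be one of {OUTCOMES}, got {outcome!r}")
    data = records
    if outcome not in data.columns and {"x1", "y1", "x2", "y2"} <= set(data.columns):
        data = migration.derive_records(data)
    if outcome not in data.columns:
        raise ParameterError(f"records lack an {outcome!r} column")
    data = data.dropna(subset=[outcome])
    if "control" not in set(data["treatment"]):
        raise ParameterError("records contain no control cells")
    vals = data[outcome].to_numpy(float)
    if np.any(vals <= 0):
        raise ParameterError(f"{outcome} must be positive for the log transform")
    X, names, levels = _design_matrix(data)
    res = fit_lmm(
        np.log(vals),
        X,
        names,
        data["litter"].to_numpy(),
        data["slice"].to_numpy(),
    )
    return FittedModel(res, outcome, levels, len(data))


def fit_count_model(counts: pd.DataFrame, count_col: str = "n_outside") -> FittedModel:
    """Per-slice migrated-count model: log(count + 1), litter random intercept."""
    for col in ("litter", "treatment", count_col):
        if col not in counts.columns:
            raise ParameterError(f"count table lacks column {col!r}")
    if "control" not in set(counts["treatment"]):
        raise ParameterError("count table contains no control slices")
    vals = counts[count_col].to_numpy(float)
    if np.any(vals < 0):
        raise ParameterError("counts must be non-negative")
    if np.any(vals == 0):
        import logging

        logging.getLogger(__name__).warning(
            "zero counts present; log(count+1) keeps them but estimates may sit near a boundary"
        )
    X, names, levels = _design_matrix(counts)
    res = fit_lmm(np.log1p(vals), X, names, counts["litter"].to_numpy(), None)
    return FittedModel(res, f"log1p[{count_col}]", levels, len(counts))


@dataclass
class GatedResult:
    """Family-level F gates plus conditional member-level Wald comparisons."""

    outcome: str
    alpha: float
    family_table: pd.DataFrame
    wald_table: pd.DataFrame
    warnings: list[str] = field(default_factory=list)

    def gate_open(self, family: str) -> bool:
        row = self.family_table[self.family_table["family"] == family]
        return bool(row["gate_open"].iloc[0]) if len(row) else False


def _family_f_test(model: FittedModel, members: tuple[str, ...]):
    L = np.stack([model._contrast(m) for m in members])
    beta = model.lmm.beta.to_numpy()
    M = L @ model.lmm.cov_beta @ L.T
    q = len(members)
    fval = float(beta @ L.T @ np.linalg.solve(M, L @ beta)) / q
    df_den = satterthwaite_df_multi(model.lmm, L)
    method = "satterthwaite"
    if df_den is None or not np.isfinite(df_den):
        df_den = float(model.lmm.df_containment)
        method = "containment"
    p = float(stats.f.sf(fval, q, df_den))
    return fval, q, float(df_den), p, method


def family_gate(
    model: FittedModel,
    families: TreatmentFamilies | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> GatedResult:
    """Per-family joint F-test; member Wald tests only where the gate opens.

    A family with any configured member missing from the fitted data is
    skipped with a warning. Wald rows exist only for open gates.
    """
    if not 0 < alpha < 1:
        raise ParameterError(f"alpha must lie in (0, 1), got {alpha}")
    families = families or TreatmentFamilies()
    present = set(model.treatments)
    fam_rows = []
    wald_rows = []
    warnings_log: list[str] = []
    for fam, members in families.families.items():
        missing = [m for m in members if m not in present]
        if missing:
            warnings_log.append(f"family {fam!r} skipped: members absent from data: {missing}")
            continue
        fval, q, df_den, p, method = _family_f_test(model, members)
        open_ = p < alpha
        fam_rows.append(
            {
                "family": fam,
                "members": ",".join(members),
                "F": fval,
                "df_num": q,
                "df_den": df_den,
                "p": p,
                "gate_open": open_,
                "df_method": method,
            }
        )
        if not open_:
            continue
        for m in members:
            est, se = model.coefficient(m)
            df = satterthwaite_df_scalar(model.lmm, model._contrast(m))
            if df is None or not np.isfinite(df):
                df = float(model.lmm.df_containment)
            tstat = est / se
            wald_rows.append(
                {
                    "family": fam,
                    "treatment": m,
                    "log_effect": est,
                    "se": se,
                    "ratio": float(np.exp(est)),
                    "t": tstat,
                    "df": float(df),
                    "p": float(2 * stats.t.sf(abs(tstat), df)),
                }
            )
    family_table = pd.DataFrame(
        fam_rows,
        columns=["family", "members", "F", "df_num", "df_den", "p", "gate_open", "df_method"],
    )
    wald_table = pd.DataFrame(
        wald_rows,
        columns=["family", "treatment", "log_effect", "se", "ratio", "t", "df", "p"],
    )
    return GatedResult(model.outcome, alpha, family_table, wald_table, warnings_log)


def ungated_member_tests(
    model: FittedModel, families: TreatmentFamilies | None = None
) -> pd.DataFrame:
    """Per-member Wald tests without the family gate (for calibration studies)."""
    families = families or TreatmentFamilies()
    rows = []
    present = set(model.treatments)
    for fam, members in families.families.items():
        for m in members:
            if m not in present:
                continue
            est, se = model.coefficient(m)
            df = satterthwaite_df_scalar(model.lmm, model._contrast(m))
            if df is None or not np.isfinite(df):
                df = float(model.lmm.df_containment)
            tstat = est / se
            rows.append(
                {
                    "family": fam,
                    "treatment": m,
                    "t": tstat,
                    "df": float(df),
                    "p": float(2 * stats.t.sf(abs(tstat), df)),
                }
            )
    return pd.DataFrame(rows, columns=["family", "treatment", "t", "df", "p"])


# ---------------------------------------------------------------------------
# simple two-group tests and paired-t power
# ---------------------------------------------------------------------------

def two_group_ttest(x, y, paired: bool = False) -> tuple[float, float, float]:
    """Standard two-sided t-test; returns (t, df, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ParameterError("need >= 2 observations per group")
    if np.var(x) == 0 and np.var(y) == 0:
        if np.allclose(x.mean(), y.mean()):
            return 0.0, float(len(x) + len(y) - 2), 1.0
        raise ComputationError("zero variance in both groups with unequal means")
    if paired:
        if len(x) != len(y):
            raise ParameterError("paired samples must have equal length")
        res = stats.ttest_rel(x, y)
        df = len(x) - 1
    else:
        res = stats.ttest_ind(x, y, equal_var=True)
        df = len(x) + len(y) - 2
    return float(res.statistic), float(df), float(res.pvalue)


def paired_t_power(n: int, d: float, alpha: float = 0.05, two_sided: bool = True) -> float:
    """Power of the paired t-test at standardized effect d with n pairs."""
    if n < 2:
        raise ParameterError("need n >= 2 pairs")
    if not 0 < alpha < 1:
        raise ParameterError("alpha must lie in (0, 1)")
    df = n - 1
    ncp = d * np.sqrt(n)
    if two_sided:
        tcrit = stats.t.ppf(1 - alpha / 2, df)
        upper = stats.nct.sf(tcrit, df, ncp)
        lower = stats.nct.cdf(-tcrit, df, ncp)
        # scipy's nct lower tail underflows to nan at large df x ncp; it is ~0 there
        if not np.isfinite(lower):
            lower = 0.0
        power = upper + lower
    else:
        tcrit = stats.t.ppf(1 - alpha, df)
        power = stats.nct.sf(tcrit, df, ncp)
    if not np.isfinite(power):
        raise ComputationError("noncentral-t power evaluation failed")
    return float(power)


def paired_t_detectable_effect(
    n: int,
    alpha: float = 0.05,
    power: float = 0.80,
    two_sided: bool = True,
) -> float:
    """Smallest standardized effect size with paired-t power >= target.

    Solved by noncentral-t root finding on the power curve.
    """
    if n < 2:
        raise ParameterError("need n >= 2 pairs")
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ParameterError("alpha and power must lie in (0, 1)")

    def gap(d):
        return paired_t_power(n, d, alpha, two_sided) - power

    lo, hi = 1e-9, 1.0
    while gap(hi) < 0:
        hi *= 2
        if hi > 1e4:
            raise ComputationError("detectable-effect search failed to bracket a root")
    return float(optimize.brentq(gap, lo, hi, xtol=1e-10))
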