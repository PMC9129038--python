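"""Statistical models linking border distance, genotype and expression.

The battery mirrors the study design for allele-level tables:

* :class:`DistanceModel` — ordinary least squares of signed distance on a
  categorical predictor (genotype or near/far rank) controlling for
  nuclear volume.  The headline contrast "maternal alleles sit further
  from the border than paternal alleles" is its predictor slope.
* :class:`MixedDistanceModel` — linear mixed model of distance on the
  number of expressed alleles per cell (0/1/2, reference 0) plus volume,
  with a per-cell random intercept for the repeated alleles of one
  nucleus.
* :class:`ExpressionModel` — logistic regression of the expression state
  on distance plus volume, optionally with cluster-robust (per-cell)
  standard errors.
* :func:`fisher_near_far` and :func:`shell_chisq` — the exact and
  chi-squared contingency tests of peripheral enrichment.

Every ``fit`` returns a :class:`ModelResult` carrying the per-term
estimate, SE, statistic, df and p-value, plus ``summary()``.
No multiple-testing correction is applied anywhere; p-values are reported
unadjusted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps


@dataclass
class ModelResult:
    """Fitted-model term table plus bookkeeping.

    ``terms`` columns: estimate, se, statistic, df, pvalue; the statistic
    is t for linear/mixed families and z for logistic.
    """

    family: str                  # linear | mixed | logistic
    formula: str
    terms: pd.DataFrame
    n_obs: int
    n_cells: int | None = None
    random_intercept_sd: float | None = None
    notes: list[str] = field(default_factory=list)

    def term(self, name: str) -> pd.Series:
        matches = [t for t in self.terms.index if name in t]
        if not matches:
            raise KeyError(f"no term matching {name!r} in {list(self.terms.index)}")
        return self.terms.loc[matches[0]]

    def conf_int(self, name: str, alpha: float = 0.05) -> tuple[float, float]:
        row = self.term(name)
        df = row["df"] if np.isfinite(row["df"]) else np.inf
        q = sps.t.ppf(1 - alpha / 2, df) if np.isfinite(df) else sps.norm.ppf(1 - alpha / 2)
        return (row["estimate"] - q * row["se"], row["estimate"] + q * row["se"])

    def summary(self) -> str:
        lines = [f"{self.family} model: {self.formula}",
                 f"n_obs = {self.n_obs}"
                 + (f", n_cells = {self.n_cells}" if self.n_cells else "")]
        if self.random_intercept_sd is not None:
            lines.append(f"random intercept SD (cell) = "
                         f"{self.random_intercept_sd:.4f} um")
        stat = "t" if self.family in ("linear", "mixed") else "z"
        lines.append(f"{'term':<32}{'estimate':>10}{'SE':>10}"
                     f"{stat:>8}{'df':>8}{'p':>10}")
        for name, row in self.terms.iterrows():
            df_s = f"{row['df']:.0f}" if np.isfinite(row["df"]) else "inf"
            lines.append(f"{name:<32}{row['estimate']:>10.4f}{row['se']:>10.4f}"
                         f"{row['statistic']:>8.3f}{df_s:>8}{row['pvalue']:>10.4g}")
        lines.extend(self.notes)
        return "\n".join(lines)


def _term_table(params, bse, stats_, df, pvalues) -> pd.DataFrame:
    return pd.DataFrame({
        "estimate": params,
        "se": bse,
        "statistic": stats_,
        "df": df,
        "pvalue": pvalues,
    })


def _check_table(table: pd.DataFrame, cols) -> None:
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"table is missing columns {missing}")
    if table[list(cols)].isna().any().any():
        raise ValueError("table has missing values in model columns")


def _pick_reference(levels: list[str]) -> str:
    # paternal-pattern group (or the near allele) as reference so the
    # maternal/far coefficient is positive toward the nuclear interior
    for preferred in ("matrepKO", "matIGDMRKO", "near"):
        if preferred in levels:
            return preferred
    return sorted(levels)[0]


class DistanceModel:
    """OLS of signed border distance on a factor, adjusted for volume.

    ``distance_um ~ C(predictor, Treatment(reference)) + volume_um3``.
    The default reference level is the paternal-pattern group (matrepKO /
    matIGDMRKO) or the "near" allele when ranking is the predictor, so
    the reported slope is positive when the other level lies deeper in
    the nucleus.
    """

    def __init__(self, table: pd.DataFrame, predictor: str = "genotype",
                 covariate: str | None = "volume_um3",
                 response: str = "distance_um",
                 reference: str | None = None) -> None:
        _check_table(table, [response, predictor] + ([covariate] if covariate else []))
        levels = sorted(table[predictor].unique().tolist())
        if len(levels) < 2:
            raise ValueError(f"predictor {predictor!r} has a single level: {levels}")
        self.table = table
        self.predictor = predictor
        self.covariate = covariate
        self.response = response
        if reference is None:
            str_levels = [str(lv) for lv in levels]
            picked = _pick_reference(str_levels)
            reference = levels[str_levels.index(picked)]
        if reference not in levels:
            raise ValueError(f"reference {reference!r} not among {levels}")
        self.reference = reference
        self.formula = (f"{response} ~ C({predictor}, "
                        f"Treatment(reference={reference!r}))"
                        + (f" + {covariate}" if covariate else ""))

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, **kw) -> "DistanceModel":
        return cls(table, **kw)

    def fit(self) -> ModelResult:
        res = smf.ols(self.formula, data=self.table).fit()
        if np.linalg.matrix_rank(res.model.exog) < res.model.exog.shape[1]:
            raise ValueError("design matrix is rank deficient")
        terms = _term_table(res.params, res.bse, res.tvalues,
                            np.full(len(res.params), res.df_resid),
                            res.pvalues)
        terms.index = _clean_terms(terms.index, self.predictor)
        return ModelResult("linear", self.formula, terms, int(res.nobs))


class MixedDistanceModel:
    """Linear mixed model: distance on expression count with a per-cell
    random intercept.

    The expression count (0, 1 or 2 expressed alleles in the cell) is
    computed from the table when absent and dummy-coded with 0 as
    reference.  Degrees of freedom for the t tests use a containment-style
    approximation, ``n_obs - n_cells - rank + 1``; estimates and SEs come
    from the REML fit.  If every cell contributes a single allele the
    model degenerates and an OLS fit is returned with a warning note.
    """

    def __init__(self, table: pd.DataFrame, fixed: str | None = None,
                 covariate: str | None = "volume_um3",
                 response: str = "distance_um",
                 cell_key: str = "cell_id") -> None:
        _check_table(table, [response, cell_key] + ([covariate] if covariate else []))
        table = table.copy()
        if fixed is None:
            fixed = "n_expressed"
            if "n_expressed" not in table.columns:
                _check_table(table, ["expressed"])
                counts = table.groupby(cell_key)["expressed"].transform("sum")
                table["n_expressed"] = counts.astype(int)
        self.table = table
        self.cell_key = cell_key
        self.response = response
        self.fixed = fixed
        rhs = (f"C({fixed})" if table[fixed].nunique() > 2 or
               table[fixed].dtype == object else fixed)
        self.formula = f"{response} ~ {rhs}" + (f" + {covariate}" if covariate else "")

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, **kw) -> "MixedDistanceModel":
        return cls(table, **kw)

    def fit(self) -> ModelResult:
        n_cells = int(self.table[self.cell_key].nunique())
        if (self.table.groupby(self.cell_key).size() == 1).all():
            res = smf.ols(self.formula, data=self.table).fit()
            terms = _term_table(res.params, res.bse, res.tvalues,
                                np.full(len(res.params), res.df_resid),
                                res.pvalues)
            terms.index = _clean_terms(terms.index, self.fixed)
            out = ModelResult("linear", self.formula, terms, int(res.nobs),
                              n_cells=n_cells)
            out.notes.append("note: all cells singleton; fixed-effects fit")
            warnings.warn("all cells contribute one allele; "
                          "falling back to a fixed-effects fit")
            return out

        model = smf.mixedlm(self.formula, data=self.table,
                            groups=self.table[self.cell_key])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = model.fit(reml=True)
            except np.linalg.LinAlgError:
                res = model.fit(reml=True, method="powell")
        params = res.fe_params
        bse = res.bse_fe
        tvals = params / bse
        rank = len(params)
        df = max(int(res.nobs) - n_cells - rank + 1, 1)
        pvals = 2 * sps.t.sf(np.abs(tvals), df)
        terms = _term_table(params, bse, tvals, np.full(rank, float(df)), pvals)
        terms.index = _clean_terms(terms.index, self.fixed)
        re_sd = float(np.sqrt(max(res.cov_re.iloc[0, 0], 0.0)))
        return ModelResult("mixed", self.formula, terms, int(res.nobs),
                           n_cells=n_cells, random_intercept_sd=re_sd)


class ExpressionModel:
    """Logistic regression of expression state on distance and volume.

    With ``cluster=True`` the standard errors are cluster-robust by cell,
    accounting for the two correlated alleles a nucleus contributes.
    Complete separation raises with a diagnostic.
    """

    def __init__(self, table: pd.DataFrame, predictor: str = "distance_um",
                 covariate: str | None = "volume_um3",
                 outcome: str = "expressed", cluster: bool = False,
                 cell_key: str = "cell_id") -> None:
        _check_table(table, [outcome, predictor] + ([covariate] if covariate else []))
        if table[outcome].astype(bool).nunique() < 2:
            raise ValueError(f"outcome {outcome!r} has a single class")
        self.table = table.assign(**{outcome: table[outcome].astype(int)})
        self.formula = f"{outcome} ~ {predictor}" + (f" + {covariate}" if covariate else "")
        self.cluster = cluster
        self.cell_key = cell_key

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, **kw) -> "ExpressionModel":
        return cls(table, **kw)

    def fit(self) -> ModelResult:
        model = smf.logit(self.formula, data=self.table)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
                if self.cluster:
                    res = model.fit(disp=0, cov_type="cluster",
                                    cov_kwds={"groups": self.table[self.cell_key]})
                else:
                    res = model.fit(disp=0)
        except (sm.tools.sm_exceptions.PerfectSeparationError,
                sm.tools.sm_exceptions.PerfectSeparationWarning) as err:
            raise ValueError(
                "complete separation: the outcome is perfectly predicted; "
                "the logistic coefficients are unbounded"
            ) from err
        terms = _term_table(res.params, res.bse, res.tvalues,
                            np.full(len(res.params), np.inf), res.pvalues)
        n_cells = (int(self.table[self.cell_key].nunique())
                   if self.cell_key in self.table.columns else None)
        out = ModelResult("logistic", self.formula, terms, int(res.nobs),
                          n_cells=n_cells)
        if self.cluster:
            out.notes.append("cluster-robust SEs by cell")
        return out


def _clean_terms(index, predictor: str):
    """Shorten patsy's C(...)[T.level] labels to predictor[level]."""
    out = []
    for name in index:
        if name.startswith("C(") and "[T." in name:
            level = name.split("[T.")[1].rstrip("]")
            out.append(f"{predictor}[{level}]")
        else:
            out.append(name)
    return out


# ---------------------------------------------------------------------------
# Contingency tests
# ---------------------------------------------------------------------------

def _fisher_p(counts: np.ndarray) -> float:
    """Two-sided Fisher exact p-value (the p-value path of
    :func:`fisher_near_far`)."""
    return float(sps.fisher_exact(counts, alternative="two-sided")[1])


def fisher_near_far(table: np.ndarray | pd.DataFrame) -> tuple[float, float]:
    """Two-sided Fisher exact test of a 2x2 near/far x expressed table.

    Returns ``(log2 odds ratio, p)``; the odds ratio is the conditional
    maximum-likelihood estimate.  A zero cell yields a +/-inf log2 OR
    with the exact p-value still defined.
    """
    counts = np.asarray(table)
    if counts.shape != (2, 2):
        raise ValueError(f"need a 2x2 table, got shape {counts.shape}")
    if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.number):
        raise ValueError("counts must be non-negative numbers")
    counts = counts.astype(int)
    res = sps.contingency.odds_ratio(counts, kind="conditional")
    p = _fisher_p(counts)
    orr = res.statistic
    if orr == 0:
        return -np.inf, p
    if np.isinf(orr):
        return np.inf, p
    return float(np.log2(orr)), p


def shell_chisq(table: np.ndarray | pd.DataFrame) -> tuple[float, int, float]:
    """Pearson chi-squared test (no continuity correction) on a 2x2 or
    2x3 expressed-by-position table.  Returns ``(chi2, df, p)``."""
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != 2 or counts.shape[1] not in (2, 3):
        raise ValueError(f"need a 2x2 or 2x3 table, got shape {counts.shape}")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("zero row/column margin: expected counts undefined")
    chi2, p, df, _ = sps.chi2_contingency(counts, correction=False)
    return float(chi2), int(df), float(p)


# ---------------------------------------------------------------------------
# Descriptive summaries
# ---------------------------------------------------------------------------

def summarize_groups(table: pd.DataFrame, keys="genotype",
                     value: str = "distance_um") -> pd.DataFrame:
    """Per-group mean, sample SD and n of the signed distance."""
    if isinstance(keys, str):
        keys = [keys]
    if table.empty:
        raise ValueError("empty table")
    g = table.groupby(list(keys))[value]
    out = g.agg(mean="mean", sd=lambda x: x.std(ddof=1), n="count")
    return out.reset_index()


def expression_state_counts(table: pd.DataFrame,
                            line_key: str = "line_id",
                            cell_key: str = "cell_id") -> pd.DataFrame:
    """Cells per line with no, monoallelic or biallelic expression."""
    per_cell = (table.groupby([line_key, cell_key])["expressed"]
                .sum().astype(int).rename("n_expressed").reset_index())
    counts = (per_cell.groupby(line_key)["n_expressed"]
              .value_counts().unstack(fill_value=0))
    counts.columns = [{0: "none", 1: "monoallelic", 2: "biallelic"}.get(c, str(c))
                      for c in counts.columns]
    return counts.reset_index()


# ---------------------------------------------------------------------------
# Functional conveniences over the model classes
# ---------------------------------------------------------------------------

def fit_distance_model(table, predictor="genotype", covariate="volume_um3",
                       **kw) -> ModelResult:
    return DistanceModel(table, predictor=predictor, covariate=covariate, **kw).fit()


def fit_mixed_distance_model(table, **kw) -> ModelResult:
    return MixedDistanceModel(table, **kw).fit()


def fit_expression_model(table, **kw) -> ModelResult:
    return ExpressionModel(table, **kw).fit()
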