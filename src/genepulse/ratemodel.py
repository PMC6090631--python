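"""Saturating Poisson model of per-gene publication rates.

The Pfeiffer-Hoffmann model predicts the number of publications on gene *i*
in year *t+1* from the gene's own cumulative publication count P_{i,t}, the
mean cumulative count over all genes of the organism P*_t, and five global
parameters::

    dP_{i,t+1} = (k1 * P*_t + k2 * P_{i,t} + k3) / (1 + (P*_t / P_S)**alpha)

``k1`` couples a gene to the growth of the whole corpus, ``k2`` is the
rich-get-richer coefficient on the gene's own history, ``k3`` is a basal
discovery rate, and the denominator saturates the publication rate once the
corpus-wide mean passes the scale ``P_S`` with sharpness ``alpha``. Annual
counts are modelled as independent Poisson draws with this mean, which gives
a likelihood that is maximised here by bounded quasi-Newton search in
log-parameter space with analytic gradients and multi-start initialisation.

Gene-years whose observed counts have a Bonferroni-significant one-sided
Poisson tail probability under the fitted model are "hot": years of
exceptional publication activity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln

from .histories import PublicationHistories

logger = logging.getLogger(__name__)

_PARAM_NAMES = ("k1", "k2", "k3", "P_S", "alpha")


@dataclass(frozen=True)
class RateModelParams:
    """The five global parameters of the publication-rate model.

    ``k1``, ``k2``, ``k3`` are annual rate coefficients (publications/year,
    per unit of the corresponding regressor); ``P_S`` is the saturation scale
    in units of mean cumulative publications per gene; ``alpha`` is the
    dimensionless saturation exponent.
    """

    k1: float
    k2: float
    k3: float
    P_S: float
    alpha: float

    def __post_init__(self) -> None:
        arr = self.as_array()
        if not np.all(np.isfinite(arr)):
            raise ValueError("rate model parameters must be finite")
        if self.k1 < 0 or self.k2 < 0 or self.k3 < 0:
            raise ValueError("rate parameters k1, k2, k3 must be non-negative")
        if self.P_S <= 0 or self.alpha <= 0:
            raise ValueError("saturation parameters P_S and alpha must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.k1, self.k2, self.k3, self.P_S, self.alpha], float)

    @classmethod
    def from_array(cls, arr) -> "RateModelParams":
        return cls(*(float(v) for v in arr))

    def to_dict(self) -> dict:
        return {n: float(v) for n, v in zip(_PARAM_NAMES, self.as_array())}

    @classmethod
    def from_dict(cls, d) -> "RateModelParams":
        return cls(**{n: d[n] for n in _PARAM_NAMES})


#: Maximum-likelihood estimates for the human gene literature, fitted on
#: 1950-2015 annual publication counts of genes never GWAS-associated.
HUMAN_ML_PARAMS = RateModelParams(k1=0.0214, k2=0.225, k3=0.00288, P_S=24.1, alpha=1.67)


def predict_rate(params: RateModelParams, P_star, P_i):
    """Predicted publications next year given current cumulative counts.

    Vectorised over ``P_star`` (cohort mean cumulative) and ``P_i`` (the
    gene's cumulative count); both must be non-negative.
    """
    P_star = np.asarray(P_star, float)
    P_i = np.asarray(P_i, float)
    if (P_star < 0).any() or (P_i < 0).any():
        raise ValueError("cumulative publication counts must be non-negative")
    numer = params.k1 * P_star + params.k2 * P_i + params.k3
    denom = 1.0 + (P_star / params.P_S) ** params.alpha
    out = numer / denom
    return out if out.ndim else float(out)


def poisson_tail(observed, mean):
    """One-sided Poisson tail probability P(X >= observed) for X ~ Poisson(mean).

    Uses the regularized incomplete gamma function through ``poisson.sf``,
    which stays accurate far into the tail (no ``1 - cdf`` cancellation).
    ``observed`` of 0 returns 1 exactly.
    """
    observed = np.asarray(observed)
    out = stats.poisson.sf(observed - 1, mean)
    return out if out.ndim else float(out)


def poisson_log_tail(observed, mean):
    """``log`` of :func:`poisson_tail`, safe where the tail underflows."""
    observed = np.asarray(observed)
    out = stats.poisson.logsf(observed - 1, mean)
    return out if out.ndim else float(out)


class PublicationRateModel:
    """Poisson likelihood of annual publication counts under the rate model.

    Parameters
    ----------
    histories : PublicationHistories
        Annual counts for the full gene universe. Cumulative counts (with
        pre-range baselines folded in) supply both the per-gene regressor and
        the cohort mean.
    fit_genes : sequence, optional
        Genes whose counts enter the likelihood (e.g. all genes never
        GWAS-associated). Default: every gene.
    cohort_genes : sequence, optional
        Genes over which the cohort mean P*_t is averaged. Default: the full
        universe, including zero-publication genes.
    fit_years : (int, int)
        Calendar years whose counts enter the likelihood; intersected with
        the data range. The first fit year is predicted from the pre-range
        baseline state.
    cohort_means : pandas.Series, optional
        Externally supplied P*_t (indexed by the year being predicted *from*,
        i.e. ``cohort_means[t]`` drives the count of year ``t+1``). Overrides
        ``cohort_genes``.
    """

    def __init__(
        self,
        histories: PublicationHistories,
        fit_genes=None,
        cohort_genes=None,
        fit_years: tuple[int, int] = (1950, 2015),
        cohort_means: pd.Series | None = None,
        eps: float = 1e-10,
    ) -> None:
        self.histories = histories
        self.eps = float(eps)
        lo, hi = histories.year_range
        y0, y1 = max(fit_years[0], lo), min(fit_years[1], hi)
        if y0 > y1:
            raise ValueError("fit_years do not overlap the data range")
        self.fit_years = np.arange(y0, y1 + 1)

        cum = histories.cumulative()
        # prior cumulative: state at the end of year y-1 drives the count of year y
        prior = cum.shift(1, axis=1)
        prior.iloc[:, 0] = histories.baseline
        prior = prior.loc[:, y0:y1]

        if fit_genes is None:
            fit_genes = histories.genes
        self.fit_genes = pd.Index(fit_genes)
        if len(self.fit_genes) == 0:
            raise ValueError("no genes to fit")
        self._C = histories.counts.loc[self.fit_genes, y0:y1].to_numpy(float)
        self._P = prior.loc[self.fit_genes].to_numpy(float)

        if cohort_means is not None:
            self._S = cohort_means.reindex(self.fit_years - 1).to_numpy(float)
            if np.isnan(self._S).any():
                raise ValueError(
                    "cohort_means must cover every year preceding a fit year"
                )
        else:
            if cohort_genes is None:
                cohort_genes = histories.genes
            self._S = prior.loc[pd.Index(cohort_genes)].mean(axis=0).to_numpy(float)
        if np.any(np.diff(self._S) < -1e-9):
            raise ValueError("cohort mean cumulative counts must be non-decreasing")
        self._lgam = gammaln(self._C + 1.0).sum()

    @property
    def nobs(self) -> int:
        return self._C.size

    # -- likelihood ---------------------------------------------------------

    def _mu(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        k1, k2, k3, ps, alpha = theta
        with np.errstate(over="ignore"):
            R = (self._S / ps) ** alpha  # per-year saturation ratio
        D = 1.0 + R
        N = k1 * self._S + k2 * self._P + k3
        return N / D, N, R, D

    def loglike(self, params) -> float:
        """Summed Poisson log-likelihood of the fitted counts."""
        theta = params.as_array() if isinstance(params, RateModelParams) else np.asarray(params, float)
        mu, _, _, _ = self._mu(theta)
        mu = np.maximum(mu, self.eps)
        return float((self._C * np.log(mu) - mu).sum() - self._lgam)

    def _negll_and_grad(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        """Negative log-likelihood and gradient w.r.t. log-parameters."""
        theta = np.exp(x)
        k1, k2, k3, ps, alpha = theta
        mu_raw, N, R, D = self._mu(theta)
        mu = np.maximum(mu_raw, self.eps)
        nll = -((self._C * np.log(mu) - mu).sum() - self._lgam)

        w = self._C / mu - 1.0
        w = np.where(mu_raw >= self.eps, w, 0.0)  # clipped cells carry no gradient
        wcol = w.sum(axis=0)
        wN = (w * N).sum(axis=0)
        wP = (w * self._P).sum(axis=0)
        invD = 1.0 / D
        g_k1 = float((self._S * invD * wcol).sum())
        g_k2 = float((invD * wP).sum())
        g_k3 = float((invD * wcol).sum())
        # R / D^2 computed as (R/D) * (1/D), stable when R overflows to inf
        with np.errstate(invalid="ignore"):
            RinvD = np.where(np.isinf(R), 1.0, R * invD)
        # d mu / d P_S = N * alpha * R / (P_S * D^2)
        g_ps = float((alpha / ps) * (RinvD * invD * wN).sum())
        # d mu / d alpha = -N * R * log(S/P_S) / D^2 ; zero where S == 0
        with np.errstate(divide="ignore", invalid="ignore"):
            lnratio = np.where(self._S > 0, np.log(self._S / ps), 0.0)
        g_alpha = float(-(RinvD * lnratio * invD * wN).sum())
        grad = -np.array([g_k1, g_k2, g_k3, g_ps, g_alpha]) * theta  # chain rule to log-space
        return nll, grad

    # -- fitting -------------------------------------------------------------

    def fit(
        self,
        starts: int = 5,
        seed: int = 0,
        bounds: tuple[float, float] = (1e-6, 1e3),
        init: RateModelParams | None = None,
        maxiter: int = 500,
    ) -> "PublicationRateResults":
        """Maximise the Poisson likelihood over the five parameters.

        Runs L-BFGS-B in log-parameter space from ``starts`` initial points
        (a data-informed default plus log-uniform random draws, seeded) and
        keeps the best converged optimum.
        """
        if self._C.shape[0] < 2 or self._C.shape[1] < 2:
            raise ValueError("fitting needs at least 2 genes and 2 years of counts")
        rng = np.random.default_rng(seed)
        lo, hi = np.log(bounds[0]), np.log(bounds[1])
        mean_count = self._C.mean()
        s_top = max(self._S.max(), 1.0)
        if init is None:
            init = RateModelParams(
                k1=0.01, k2=0.1, k3=max(mean_count, 1e-4), P_S=s_top, alpha=1.0
            )
        inits = [np.log(np.clip(init.as_array(), bounds[0], bounds[1]))]
        # random multi-starts, log-uniform over a broad plausible box
        ra, rb = np.log(1e-4), np.log(1e2)
        for _ in range(max(starts - 1, 0)):
            inits.append(rng.uniform(ra, rb, size=5))

        results = []
        for x0 in inits:
            res = optimize.minimize(
                self._negll_and_grad,
                x0,
                jac=True,
                method="L-BFGS-B",
                bounds=[(lo, hi)] * 5,
                options={"maxiter": maxiter},
            )
            results.append(res)
        ok = [r for r in results if r.success and np.isfinite(r.fun)]
        if not ok:
            msgs = "; ".join(str(r.message) for r in results)
            raise RuntimeError(f"rate-model fit failed to converge from any start: {msgs}")
        best = min(ok, key=lambda r: r.fun)
        params = RateModelParams.from_array(np.exp(best.x))

        at_lower = np.exp(best.x) <= bounds[0] * (1 + 1e-6)
        notes = []
        if self._C.sum() == 0:
            notes.append(
                "all counts are zero: rate parameters driven to the lower bound; "
                "saturation parameters P_S and alpha are unidentifiable"
            )
        elif at_lower[:3].all():
            notes.append("all rate parameters at the lower bound")
        return PublicationRateResults(
            model=self,
            params=params,
            llf=-float(best.fun),
            converged=True,
            n_starts=len(inits),
            start_llfs=[-float(r.fun) for r in results if np.isfinite(r.fun)],
            notes=notes,
        )


@dataclass
class PublicationRateResults:
    """Maximum-likelihood fit of :class:`PublicationRateModel`."""

    model: PublicationRateModel
    params: RateModelParams
    llf: float
    converged: bool
    n_starts: int
    start_llfs: list = field(default_factory=list)
    notes: list = field(default_factory=list)

    def predict(
        self,
        histories: PublicationHistories | None = None,
        years: tuple[int, int] | None = None,
        cohort_genes=None,
    ) -> pd.DataFrame:
        """Expected annual publication counts under the fitted model.

        Defaults to the model's own histories and fit window, with P*_t from
        the full universe; pass other ``histories`` to score held-out genes.
        """
        h = histories if histories is not None else self.model.histories
        lo, hi = h.year_range
        if years is None:
            years = (int(self.model.fit_years[0]), int(self.model.fit_years[-1]))
        y0, y1 = max(years[0], lo), min(years[1], hi)
        cum = h.cumulative()
        prior = cum.shift(1, axis=1)
        prior.iloc[:, 0] = h.baseline
        prior = prior.loc[:, y0:y1]
        cohort = prior if cohort_genes is None else prior.loc[pd.Index(cohort_genes)]
        S = cohort.mean(axis=0).to_numpy(float)
        mu = predict_rate(self.params, S[None, :], prior.to_numpy(float))
        return pd.DataFrame(mu, index=h.genes, columns=prior.columns)

    def hot_gene_scan(
        self,
        histories: PublicationHistories | None = None,
        first_gwas_year: pd.Series | None = None,
        alpha: float = 0.05,
        n_genes: int | None = None,
        n_years: int | None = None,
        years: tuple[int, int] | None = None,
        recent_window: int = 3,
    ) -> "HotGeneScan":
        """Bonferroni-corrected scan for gene-years with excess publications.

        Each gene-year's observed count is compared with the model mean via a
        one-sided Poisson tail probability; gene-years below
        ``alpha / (n_genes * n_years)`` are flagged. ``n_genes`` and
        ``n_years`` default to the dimensions of the scanned panel.
        """
        h = histories if histories is not None else self.model.histories
        mu = self.predict(h, years=years)
        scan_years = np.asarray(mu.columns, dtype=int)
        obs = h.counts.loc[:, scan_years[0] : scan_years[-1]]
        ng = n_genes if n_genes is not None else len(h.genes)
        ny = n_years if n_years is not None else len(scan_years)
        cutoff = alpha / (ng * ny)
        tail = poisson_tail(obs.to_numpy(), np.maximum(mu.to_numpy(), self.model.eps))
        return HotGeneScan(
            observed=obs,
            expected=mu,
            tail_p=pd.DataFrame(tail, index=obs.index, columns=obs.columns),
            cutoff=cutoff,
            first_gwas_year=first_gwas_year,
            recent_window=recent_window,
            histories=h,
        )

    def summary(self) -> str:
        lines = [
            "Publication rate model (saturating Poisson), maximum likelihood",
            "=" * 64,
            f"genes fitted: {len(self.model.fit_genes)}    "
            f"years: {self.model.fit_years[0]}-{self.model.fit_years[-1]}    "
            f"gene-years: {self.model.nobs}",
            f"log-likelihood: {self.llf:.3f}    starts: {self.n_starts}",
            "-" * 64,
        ]
        for name, val in self.params.to_dict().items():
            lines.append(f"{name:>6s}  {val:12.6g}")
        for note in self.notes:
            lines.append(f"note: {note}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "llf": self.llf,
            "converged": self.converged,
            "n_starts": self.n_starts,
            "fit_years": [int(self.model.fit_years[0]), int(self.model.fit_years[-1])],
            "n_genes": len(self.model.fit_genes),
            "notes": list(self.notes),
        }


@dataclass
class HotGeneScan:
    """Result of a Bonferroni hot-gene-year scan."""

    observed: pd.DataFrame
    expected: pd.DataFrame
    tail_p: pd.DataFrame
    cutoff: float
    first_gwas_year: pd.Series | None
    recent_window: int
    histories: PublicationHistories

    @property
    def significant(self) -> pd.DataFrame:
        return self.tail_p < self.cutoff

    def _recent_gwas(self) -> pd.DataFrame:
        """Whether each gene-year falls within ``recent_window`` years of the
        gene's first GWAS association (window includes the panel year)."""
        years = np.asarray(self.observed.columns, dtype=int)
        if self.first_gwas_year is None:
            return pd.DataFrame(False, index=self.observed.index, columns=self.observed.columns)
        fg = self.first_gwas_year.reindex(self.observed.index).to_numpy(float)
        yy = years[None, :]
        fgv = fg[:, None]
        recent = (yy >= fgv) & (yy <= fgv + self.recent_window - 1)
        recent = np.where(np.isnan(fgv), False, recent)
        return pd.DataFrame(recent, index=self.observed.index, columns=self.observed.columns)

    @property
    def calls(self) -> pd.DataFrame:
        """Long-format table of the significant gene-years."""
        sig = self.significant
        recent = self._recent_gwas()
        rows = []
        for gene, year in zip(*np.nonzero(sig.to_numpy())):
            g = sig.index[gene]
            y = int(sig.columns[year])
            rows.append(
                {
                    "gene_id": g,
                    "year": y,
                    "observed": int(self.observed.iat[gene, year]),
                    "expected": float(self.expected.iat[gene, year]),
                    "tail_p": float(self.tail_p.iat[gene, year]),
                    "significant": True,
                    "recent_gwas": bool(recent.iat[gene, year]),
                    "first_gwas_year": (
                        float(self.first_gwas_year.get(g, np.nan))
                        if self.first_gwas_year is not None
                        else np.nan
                    ),
                }
            )
        cols = [
            "gene_id", "year", "observed", "expected", "tail_p",
            "significant", "recent_gwas", "first_gwas_year",
        ]
        return pd.DataFrame(rows, columns=cols)

    @property
    def any_significant(self) -> bool:
        return bool(self.significant.to_numpy().any())

    def annual_summary(self) -> pd.DataFrame:
        """Per-year counts of hot genes and hot-and-recent-GWAS genes."""
        sig = self.significant
        recent = self._recent_gwas()
        n_hot = sig.sum(axis=0)
        n_hot_recent = (sig & recent).sum(axis=0)
        new_gwas = pd.Series(0, index=sig.columns, dtype=int)
        if self.first_gwas_year is not None:
            vc = self.first_gwas_year.dropna().astype(int).value_counts()
            new_gwas = new_gwas.add(vc.reindex(new_gwas.index, fill_value=0), fill_value=0).astype(int)
        with np.errstate(invalid="ignore"):
            prop = np.where(n_hot > 0, n_hot_recent / n_hot.replace(0, np.nan), 0.0)
        out = pd.DataFrame(
            {
                "year": sig.columns.astype(int),
                "n_hot": n_hot.to_numpy(int),
                "n_hot_recent_gwas": n_hot_recent.to_numpy(int),
                "n_new_gwas_genes": new_gwas.to_numpy(int),
                "prop_hot_recent_gwas": prop.astype(float),
            }
        ).reset_index(drop=True)
        return out

    def panel(self) -> pd.DataFrame:
        """Gene-year panel for the hot-gene logistic regression.

        Columns: ``hot`` outcome, ``log10_recent`` (recent publications
        floored at 1), ``year`` (offset from the first scanned year),
        ``recent_gwas`` indicator and the year x recent-GWAS interaction.
        """
        years = np.asarray(self.observed.columns, dtype=int)
        sig = self.significant.to_numpy()
        recent_gwas = self._recent_gwas().to_numpy()
        recent_counts = np.column_stack(
            [self.histories.recent_pubs(int(y), self.recent_window).reindex(self.observed.index).to_numpy()
             for y in years]
        )
        year_off = np.broadcast_to(years - years[0], sig.shape)
        genes = np.broadcast_to(self.observed.index.to_numpy()[:, None], sig.shape)
        df = pd.DataFrame(
            {
                "gene_id": genes.ravel(),
                "year": np.broadcast_to(years, sig.shape).ravel(),
                "hot": sig.ravel().astype(int),
                "log10_recent": np.log10(np.maximum(recent_counts, 1)).ravel(),
                "year_offset": year_off.ravel().astype(float),
                "recent_gwas": recent_gwas.ravel().astype(int),
            }
        )
        df["year_x_recent_gwas"] = df["year_offset"] * df["recent_gwas"]
        return df


class SeparationError(RuntimeError):
    """Raised when the hot-gene logistic model is perfectly separated."""


def hot_logistic(panel: pd.DataFrame, ridge: float | None = None) -> pd.DataFrame:
    """Logistic regression for whether a gene-year is hot.

    Predictors: log10 recent publications, year (offset from panel start),
    recent-GWAS indicator and the year x recent-GWAS interaction. Returns a
    coefficient table (coef, std err, p). Perfect separation raises
    :class:`SeparationError`; pass ``ridge`` (an L2 penalty weight) to fit a
    ridge-stabilised model instead (no standard errors in that case).
    """
    import statsmodels.api as sm

    cols = ["log10_recent", "year_offset", "recent_gwas", "year_x_recent_gwas"]
    X = sm.add_constant(panel[cols].astype(float), has_constant="add")
    y = panel["hot"].astype(float)
    if y.nunique() < 2:
        raise SeparationError("outcome is constant: logistic model is degenerate")
    if ridge is not None:
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit_regularized(
            alpha=ridge, L1_wt=0.0
        )
        return pd.DataFrame(
            {"coef": fit.params, "std_err": np.nan, "p_value": np.nan}
        )
    with warnings.catch_warnings():
        warnings.filterwarnings("error", message=".*[Pp]erfect.*separ.*")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception as exc:  # statsmodels raises/warns various separation signals
            raise SeparationError(
                f"logistic fit failed ({exc}); consider the ridge-stabilised option"
            ) from exc
    if not np.all(np.isfinite(fit.bse)):
        raise SeparationError(
            "non-finite standard errors indicate separation; "
            "consider the ridge-stabilised option"
        )
    return pd.DataFrame(
        {"coef": fit.params, "std_err": fit.bse, "p_value": fit.pvalues}
    )


# -- thin functional surface -------------------------------------------------

def log_likelihood(
    params: RateModelParams,
    histories: PublicationHistories,
    cohort_means: pd.Series | None = None,
    fit_years: tuple[int, int] = (1950, 2015),
) -> float:
    """Poisson log-likelihood of ``histories`` under ``params``."""
    model = PublicationRateModel(histories, fit_years=fit_years, cohort_means=cohort_means)
    return model.loglike(params)


def fit_ml(
    histories: PublicationHistories,
    fit_genes=None,
    cohort_genes=None,
    fit_years: tuple[int, int] = (1950, 2015),
    starts: int = 5,
    seed: int = 0,
    **kwargs,
) -> PublicationRateResults:
    """Fit the rate model by maximum likelihood (see :class:`PublicationRateModel`)."""
    model = PublicationRateModel(
        histories, fit_genes=fit_genes, cohort_genes=cohort_genes, fit_years=fit_years
    )
    return model.fit(starts=starts, seed=seed, **kwargs)
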