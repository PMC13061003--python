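"""Bayesian heteroscedastic sigmoid dose-response model.

For one drug-assay pair with doses x (micromolar) and bioactivity y, the
model is

    y ~ Normal(mu, sigma * mu)
    mu = y1 + (y0 - y1) / (1 + exp(k * (x' - EC50)))

with x' = log10(dose) by default, so that y0 is the asymptotic bioactivity
at vanishing dose and y1 the asymptote at saturating dose (k > 0).  The
noise scale is proportional to the mean (heteroscedastic), with unitless
multiplier sigma.  The effect size is the fold change FC = y1 / y0, which
carries a Gamma(shape 5, rate 5) prior -- prior mean 1, i.e. no effect.

Hypotheses about the effect partition the FC axis at the 0.2 and 0.8
quantiles of the prior, giving prior masses (0.2, 0.6, 0.2) for the
protective / neutral / adverse hypotheses (which of the two tails is
"protective" depends on the assay's direction of benefit).  Posterior
hypothesis probabilities are fractions of posterior FC draws in each
interval; the Bayes factor reported is the posterior odds of protective
versus neutral, with evidence graded on 2*ln(BF).

Sampling uses an affine-invariant ensemble MCMC sampler; convergence is
judged on rank-normalized split-R-hat, bulk effective sample size and the
Monte Carlo standard error of each parameter, and poorly fitted datasets
are excluded rather than interpreted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DoseResponseDataset",
    "standardize",
    "fold_change_prior",
    "hypothesis_partition",
    "HypothesisPartition",
    "HypothesisResult",
    "SamplerConfig",
    "SigmoidDoseResponseModel",
    "DoseResponseResults",
    "FitCheck",
    "sigmoid_mean",
]

PARAM_NAMES = ("y0", "fc", "k", "ec50", "sigma")

EVIDENCE_GRADES = (  # thresholds on 2*ln(BF), right-open at the top
    (2.0, "none"),
    (6.0, "moderate"),
    (10.0, "strong"),
    (math.inf, "very strong"),
)


@dataclass(frozen=True)
class DoseResponseDataset:
    """Replicated bioactivity observations of one drug in one assay."""

    drug: str
    assay: str
    direction_of_benefit: str  # "increase" | "decrease"
    concentrations_uM: tuple[float, ...]
    bioactivity: tuple[float, ...]
    control_type: str = "vehicle"
    scale_factor: float = 1.0  # 1.0 until standardized

    def __post_init__(self) -> None:
        if self.direction_of_benefit not in ("increase", "decrease"):
            raise ValueError("direction_of_benefit must be 'increase' or 'decrease'")
        if self.control_type not in ("vehicle", "lesion"):
            raise ValueError("control_type must be 'vehicle' or 'lesion'")
        if len(self.concentrations_uM) != len(self.bioactivity):
            raise ValueError("concentration and bioactivity lengths differ")
        if any(c <= 0 for c in self.concentrations_uM):
            raise ValueError("concentrations must be positive")
        if len(set(self.concentrations_uM)) < 2:
            raise ValueError("need at least two distinct concentrations")

    @property
    def x(self) -> np.ndarray:
        return np.asarray(self.concentrations_uM, dtype=float)

    @property
    def y(self) -> np.ndarray:
        return np.asarray(self.bioactivity, dtype=float)

    def __len__(self) -> int:
        return len(self.bioactivity)


def standardize(dataset: DoseResponseDataset) -> DoseResponseDataset:
    """Rescale bioactivity so 10 units equal one sample standard deviation.

    The multiplier is recorded in ``scale_factor`` for back-transformation
    (original y = standardized y / scale_factor).  Doses are untouched.
    Constant y cannot be standardized and raises.
    """
    y = np.asarray(dataset.bioactivity, dtype=float)
    if len(y) < 3:
        raise ValueError("standardization needs at least 3 observations")
    sd = float(np.std(y, ddof=1))
    if sd == 0:
        raise ValueError("zero-variance bioactivity: dataset is unfittable")
    factor = 10.0 / sd
    return replace(
        dataset,
        bioactivity=tuple(v * factor for v in y),
        scale_factor=dataset.scale_factor * factor,
    )


def destandardize(dataset: DoseResponseDataset) -> DoseResponseDataset:
    """Undo standardization, restoring the original bioactivity units."""
    f = dataset.scale_factor
    return replace(
        dataset,
        bioactivity=tuple(v / f for v in dataset.bioactivity),
        scale_factor=1.0,
    )


def fold_change_prior() -> stats._distn_infrastructure.rv_frozen:
    """The Gamma(shape 5, rate 5) fold-change prior (mean 1: no effect)."""
    return stats.gamma(a=5.0, scale=1.0 / 5.0)


@dataclass(frozen=True)
class HypothesisPartition:
    """Disjoint FC intervals for the protective / neutral / adverse
    hypotheses; the neutral band is the central 60% of the prior."""

    direction_of_benefit: str
    lower: float  # 0.2 prior quantile
    upper: float  # 0.8 prior quantile

    def classify(self, fc: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Boolean masks (protective, neutral, adverse) for FC draws."""
        fc = np.asarray(fc, dtype=float)
        low = fc < self.lower
        high = fc > self.upper
        neutral = ~(low | high)
        if self.direction_of_benefit == "decrease":
            return low, neutral, high
        return high, neutral, low

    def prior_masses(self) -> tuple[float, float, float]:
        prior = fold_change_prior()
        mass_low = prior.cdf(self.lower)
        mass_high = prior.sf(self.upper)
        neutral = 1.0 - mass_low - mass_high
        if self.direction_of_benefit == "decrease":
            return mass_low, neutral, mass_high
        return mass_high, neutral, mass_low


def hypothesis_partition(direction_of_benefit: str) -> HypothesisPartition:
    """Partition FC at the 0.2/0.8 prior quantiles: prior probability 0.2 of
    a protective effect, 0.6 neutral, 0.2 adverse.  For assays whose benefit
    is a decrease in bioactivity the protective tail is FC < q(0.2); for an
    increase it is FC > q(0.8)."""
    if direction_of_benefit not in ("increase", "decrease"):
        raise ValueError("direction_of_benefit must be 'increase' or 'decrease'")
    prior = fold_change_prior()
    return HypothesisPartition(
        direction_of_benefit=direction_of_benefit,
        lower=float(prior.ppf(0.2)),
        upper=float(prior.ppf(0.8)),
    )


def sigmoid_mean(
    x: np.ndarray, y0: float | np.ndarray, y1: float | np.ndarray,
    k: float | np.ndarray, ec50: float | np.ndarray
) -> np.ndarray:
    """Logistic mean response: y0 as x -> -inf, y1 as x -> +inf (k > 0)."""
    z = np.clip(k * (x - ec50), -500, 500)
    return y1 + (y0 - y1) / (1.0 + np.exp(z))


@dataclass(frozen=True)
class SamplerConfig:
    """Ensemble-sampler settings.

    Each of ``walkers`` coupled walkers takes ``warmup`` discarded steps
    followed by ``draws`` post-warmup steps, of which every ``thin``-th is
    kept.  For convergence diagnostics the walkers are grouped
    into ``diag_chains`` pseudo-chains.  The defaults are sized so that a
    well-specified dataset passes the default convergence gate (R-hat 1.01,
    bulk ESS 400) with margin; ensemble moves mix these weakly identified
    sigmoid posteriors slowly, so the step counts are deliberately large.
    """

    draws: int = 6000
    warmup: int = 6000
    walkers: int = 32
    seed: int = 0
    thin: int = 6
    diag_chains: int = 4


@dataclass
class FitCheck:
    passed: bool
    reasons: list[str] = field(default_factory=list)


@dataclass
class HypothesisResult:
    p_protective: float
    p_neutral: float
    p_adverse: float
    bf: float
    two_log_bf: float
    evidence_grade: str
    prior_corrected_bf: float
    bf_infinite: bool = False
    excluded: bool = False
    exclusion_reason: str = ""


def _evidence_grade(two_log_bf: float) -> str:
    for upper, grade in EVIDENCE_GRADES:
        if two_log_bf <= upper:
            return grade
    return "very strong"


class SigmoidDoseResponseModel:
    """Bayesian sigmoid dose-response model for one (standardized) dataset.

    Parameters are sampled on the natural scale: y0 (zero-dose asymptote,
    truncated-normal prior centered on the lowest-dose sample mean with
    scale three sample standard deviations, truncated at 0), FC (the
    Gamma(5, 5) fold-change prior; y1 = FC * y0), slope k (half-normal,
    scale 5), EC50 (uniform over the observed log-dose range padded by one
    decade) and sigma (half-normal, scale 0.5).  Positivity of y0 and FC
    keeps the mean response positive, which makes sigma * mu a valid noise
    scale.

    Parameters
    ----------
    dataset : DoseResponseDataset
        Standardized observations (see :func:`standardize`).
    x_scale : {"log10", "linear"}
        Dose axis handed to the logistic; log10 by default because tested
        concentrations span decades and the zero-dose asymptote is only
        reachable on a log axis.
    y0_prior : (loc, scale), optional
        Override the data-driven y0 prior (used e.g. by calibration studies
        that must generate from the exact fitted prior).
    """

    k_prior_scale = 5.0
    sigma_prior_scale = 0.5
    ec50_pad = 1.0

    def __init__(
        self,
        dataset: DoseResponseDataset,
        *,
        x_scale: str = "log10",
        y0_prior: tuple[float, float] | None = None,
    ) -> None:
        if x_scale not in ("log10", "linear"):
            raise ValueError("x_scale must be 'log10' or 'linear'")
        self.dataset = dataset
        self.x_scale = x_scale
        self.x = np.log10(dataset.x) if x_scale == "log10" else dataset.x
        self.y = dataset.y
        if y0_prior is None:
            lowest = dataset.x == dataset.x.min()
            loc = float(np.mean(self.y[lowest]))
            scale = 3.0 * float(np.std(self.y, ddof=1))
            y0_prior = (loc, max(scale, 1e-6))
        self.y0_prior = y0_prior
        self.ec50_bounds = (self.x.min() - self.ec50_pad, self.x.max() + self.ec50_pad)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        drug: str,
        assay: str,
        *,
        standardized: bool = True,
        **kwargs,
    ) -> "SigmoidDoseResponseModel":
        """Build a model from the long-format dose-response table (columns
        drug, assay, direction_of_benefit, control_type, concentration_uM,
        bioactivity)."""
        sub = df[(df["drug"] == drug) & (df["assay"] == assay)]
        if sub.empty:
            raise KeyError(f"no rows for drug {drug!r}, assay {assay!r}")
        ds = DoseResponseDataset(
            drug=drug,
            assay=assay,
            direction_of_benefit=str(sub["direction_of_benefit"].iloc[0]),
            control_type=str(sub["control_type"].iloc[0]),
            concentrations_uM=tuple(float(v) for v in sub["concentration_uM"]),
            bioactivity=tuple(float(v) for v in sub["bioactivity"]),
        )
        if standardized:
            ds = standardize(ds)
        return cls(ds, **kwargs)

    # --- log posterior (vectorized over an ensemble of parameter vectors) ---

    def log_posterior(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        y0, fc, k, ec50, sigma = theta.T
        lp = np.zeros(len(theta))

        loc0, scale0 = self.y0_prior
        lo, hi = self.ec50_bounds
        invalid = (
            (y0 <= 0) | (fc <= 0) | (k <= 0) | (sigma <= 0)
            | (ec50 < lo) | (ec50 > hi)
        )
        valid = ~invalid
        lp[invalid] = -np.inf
        if not np.any(valid):
            return lp if theta.ndim == 2 else lp[0]

        v = valid
        lp[v] += -0.5 * ((y0[v] - loc0) / scale0) ** 2
        lp[v] += (5.0 - 1.0) * np.log(fc[v]) - 5.0 * fc[v]
        lp[v] += -0.5 * (k[v] / self.k_prior_scale) ** 2
        lp[v] += -0.5 * (sigma[v] / self.sigma_prior_scale) ** 2

        y1 = fc[v] * y0[v]
        mu = sigmoid_mean(self.x[None, :], y0[v, None], y1[:, None],
                          k[v, None], ec50[v, None])
        sd = sigma[v, None] * mu
        resid = (self.y[None, :] - mu) / sd
        lp[v] += np.sum(-0.5 * resid**2 - np.log(sd), axis=1)
        return lp

    def _initial_ensemble(self, walkers: int, rng: np.random.Generator) -> np.ndarray:
        x, y = self.x, self.y
        low_mask = x == x.min()
        high_mask = x == x.max()
        y0_hat = max(float(np.mean(y[low_mask])), 1e-3)
        y1_hat = max(float(np.mean(y[high_mask])), 1e-3)
        fc_hat = min(max(y1_hat / y0_hat, 0.05), 5.0)
        center = np.array([y0_hat, fc_hat, 1.0, float(np.median(x)), 0.2])
        p0 = np.empty((walkers, 5))
        for i in range(walkers):
            for _ in range(100):
                cand = center * np.exp(0.1 * rng.standard_normal(5))
                cand[3] = center[3] + 0.1 * rng.standard_normal()
                if np.isfinite(self.log_posterior(cand[None, :])[0]):
                    p0[i] = cand
                    break
            else:  # pragma: no cover - ill-posed start, should not happen
                raise RuntimeError("could not initialize sampler ensemble")
        return p0

    def fit(self, config: SamplerConfig | None = None) -> "DoseResponseResults":
        """Sample the posterior and return a results object.

        Deterministic under a fixed ``config.seed``: identical data and
        settings reproduce identical sample arrays.
        """
        import emcee

        config = config or SamplerConfig()
        rng = np.random.default_rng(config.seed)
        p0 = self._initial_ensemble(config.walkers, rng)
        # differential-evolution moves mix the k/EC50 ridge far better than
        # the default stretch move on these posteriors
        moves = [
            (emcee.moves.DEMove(), 0.8),
            (emcee.moves.DESnookerMove(), 0.2),
        ]
        sampler = emcee.EnsembleSampler(
            config.walkers, 5, self.log_posterior, vectorize=True, moves=moves
        )
        sampler._random = np.random.RandomState(
            rng.integers(0, 2**31 - 1)
        )
        sampler.run_mcmc(p0, config.warmup + config.draws, progress=False)
        chain = sampler.get_chain(discard=config.warmup, thin=config.thin)
        # (steps, walkers, 5) -> walker-major (walkers, steps, 5)
        chain = np.swapaxes(chain, 0, 1)
        return DoseResponseResults(model=self, chain=chain, config=config)


class DoseResponseResults:
    """Posterior of a fitted sigmoid dose-response model.

    ``chain`` is walker-major, shape (walkers, draws, 5) with parameters
    ordered (y0, fc, k, ec50, sigma); walkers play the role of chains in
    the convergence diagnostics.
    """

    def __init__(
        self,
        model: SigmoidDoseResponseModel,
        chain: np.ndarray,
        config: SamplerConfig,
    ) -> None:
        self.model = model
        self.chain = chain
        self.config = config
        self._diagnostics: pd.DataFrame | None = None

    # --- posterior access -------------------------------------------------

    def samples(self, name: str) -> np.ndarray:
        """Flattened posterior draws of one parameter (or 'y1')."""
        if name == "y1":
            return self.samples("fc") * self.samples("y0")
        i = PARAM_NAMES.index(name)
        return self.chain[:, :, i].reshape(-1)

    @property
    def fold_change(self) -> np.ndarray:
        return self.samples("fc")

    @property
    def posterior(self) -> dict[str, np.ndarray]:
        out = {name: self.samples(name) for name in PARAM_NAMES}
        out["y1"] = self.samples("y1")
        return out

    def fitted_curve(self, x_uM: np.ndarray) -> np.ndarray:
        """Posterior-mean response at the given micromolar doses."""
        x = np.log10(np.asarray(x_uM, float)) if self.model.x_scale == "log10" else np.asarray(x_uM, float)
        y0 = self.samples("y0")[:, None]
        y1 = self.samples("y1")[:, None]
        k = self.samples("k")[:, None]
        ec50 = self.samples("ec50")[:, None]
        return sigmoid_mean(x[None, :], y0, y1, k, ec50).mean(axis=0)

    # --- diagnostics ------------------------------------------------------

    def _grouped_chain(self) -> np.ndarray:
        """Walkers concatenated into ``diag_chains`` pseudo-chains for the
        convergence diagnostics (walkers of one ensemble are exchangeable)."""
        g = self.config.diag_chains
        w, d, p = self.chain.shape
        if w % g:
            g = 1
        return self.chain.reshape(g, (w // g) * d, p)

    @property
    def diagnostics(self) -> pd.DataFrame:
        """Per-parameter rank-normalized split-R-hat, bulk ESS, Monte Carlo
        standard error of the mean, and the posterior sd, computed on
        walker-grouped pseudo-chains."""
        if self._diagnostics is None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                import arviz as az

                grouped = self._grouped_chain()
                data = {n: grouped[:, :, i] for i, n in enumerate(PARAM_NAMES)}
                idata = az.from_dict(posterior=data)
                ess = az.ess(idata, method="bulk")
                rhat = az.rhat(idata)
                mcse = az.mcse(idata, method="mean")
            rows = {}
            for n in PARAM_NAMES:
                sd = float(np.std(self.samples(n), ddof=1))
                rows[n] = {
                    "ess": float(ess[n].values),
                    "rhat": float(rhat[n].values),
                    "mcse": float(mcse[n].values),
                    "sd": sd,
                }
            self._diagnostics = pd.DataFrame(rows).T
        return self._diagnostics

    def check_fit(
        self,
        rhat_max: float = 1.01,
        ess_min: float = 400.0,
        mcse_ratio_max: float = 0.1,
    ) -> FitCheck:
        """Convergence gate: fail on any parameter with R-hat above
        ``rhat_max``, bulk ESS below ``ess_min`` or MCSE exceeding
        ``mcse_ratio_max`` times the posterior sd."""
        diag = self.diagnostics
        reasons = []
        for name, row in diag.iterrows():
            if row["rhat"] > rhat_max:
                reasons.append(f"rhat({name}) = {row['rhat']:.3f} > {rhat_max}")
            if row["ess"] < ess_min:
                reasons.append(f"ess({name}) = {row['ess']:.0f} < {ess_min}")
            if row["sd"] > 0 and row["mcse"] / row["sd"] > mcse_ratio_max:
                reasons.append(
                    f"mcse/sd({name}) = {row['mcse'] / row['sd']:.3f} > {mcse_ratio_max}"
                )
        return FitCheck(passed=not reasons, reasons=reasons)

    # --- hypothesis testing ----------------------------------------------

    def hypothesis_test(
        self, partition: HypothesisPartition | None = None
    ) -> HypothesisResult:
        """Posterior hypothesis probabilities from the FC draws, the
        posterior-odds Bayes factor BF = P(protective | D) / P(neutral | D),
        2*ln(BF), and its evidence grade.  A secondary factor corrected for
        the unequal prior odds (0.2 vs 0.6) is also reported."""
        if partition is None:
            partition = hypothesis_partition(self.model.dataset.direction_of_benefit)
        fc = self.fold_change
        prot, neut, adv = partition.classify(fc)
        n = len(fc)
        p1, p0, p2 = prot.sum() / n, neut.sum() / n, adv.sum() / n
        infinite = p0 == 0.0
        bf = math.inf if infinite else p1 / p0
        if bf == 0.0:
            two_log_bf = -math.inf
        elif infinite:
            two_log_bf = math.inf
        else:
            two_log_bf = 2.0 * math.log(bf)
        prior_odds = 0.2 / 0.6
        return HypothesisResult(
            p_protective=p1,
            p_neutral=p0,
            p_adverse=p2,
            bf=bf,
            two_log_bf=two_log_bf,
            evidence_grade=_evidence_grade(two_log_bf),
            prior_corrected_bf=bf / prior_odds if not infinite else math.inf,
            bf_infinite=infinite,
        )

    # --- reporting --------------------------------------------------------

    def summary(self) -> pd.DataFrame:
        """Posterior summary table: mean, sd, central 90% interval and the
        convergence diagnostics for every parameter plus the derived y1."""
        rows = []
        diag = self.diagnostics
        for name in list(PARAM_NAMES) + ["y1"]:
            s = self.samples(name)
            row = {
                "parameter": name,
                "mean": float(np.mean(s)),
                "sd": float(np.std(s, ddof=1)),
                "q5": float(np.quantile(s, 0.05)),
                "q95": float(np.quantile(s, 0.95)),
            }
            if name in diag.index:
                row |= {
                    "ess": diag.loc[name, "ess"],
                    "rhat": diag.loc[name, "rhat"],
                    "mcse": diag.loc[name, "mcse"],
                }
            rows.append(row)
        return pd.DataFrame(rows).set_index("parameter")


def simulate_dataset(
    drug: str,
    assay: str,
    direction_of_benefit: str,
    doses_uM: Sequence[float],
    n_replicates: int,
    y0: float,
    fc: float,
    k: float,
    ec50: float,
    sigma: float,
    rng: np.random.Generator,
    *,
    x_scale: str = "log10",
    control_type: str = "vehicle",
) -> DoseResponseDataset:
    """Draw observations from the model's own generative process:
    y ~ Normal(mu(x), sigma * mu(x)) at the given doses."""
    doses = np.repeat(np.asarray(doses_uM, float), n_replicates)
    x = np.log10(doses) if x_scale == "log10" else doses
    mu = sigmoid_mean(x, y0, fc * y0, k, ec50)
    if np.any(mu <= 0):
        raise ValueError("parameters give non-positive mean response; noise scale invalid")
    y = rng.normal(mu, sigma * mu)
    return DoseResponseDataset(
        drug=drug,
        assay=assay,
        direction_of_benefit=direction_of_benefit,
        concentrations_uM=tuple(doses),
        bioactivity=tuple(y),
        control_type=control_type,
    )
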