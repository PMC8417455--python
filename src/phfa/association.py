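"""Internal association analysis: per-feature weighted logistic regression.

Each time-integrated feature is tested, one at a time, for association with a
binary channel label (seizure-onset zone, resected volume, or temporal lobe).
Features are first divided by their scaled median absolute deviation
(sMAD = MAD / PHI^{-1}(0.75), a robust analogue of the standard deviation), so
the fitted odds ratio reads "change in the odds per one-sMAD increase" and is
comparable across features in different units.  Observation weights make each
patient contribute equally regardless of its channel count.  Wald confidence
intervals and p-values come from the weighted GLM fit; significance tiers
apply a Bonferroni correction over the family of tests.

The model surface follows the statsmodels idiom: construct
:class:`FeatureAssociation` from a feature table and labels, call
:meth:`~FeatureAssociation.fit`, inspect the returned
:class:`AssociationResults` (``.table``, ``.summary()``).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

#: PHI^{-1}(0.75): the MAD of a standard normal, used to scale MAD to sd units.
MAD_TO_SD = float(norm.ppf(0.75))

#: Bonferroni family size used in the reference analysis: 38 features + HFO rate.
DEFAULT_N_TESTS = 39

TIER_ALPHAS = (0.05, 0.01, 0.001, 0.0001)


def smad(v: np.ndarray) -> float:
    """Scaled median absolute deviation: median(|v - median(v)|) / PHI^{-1}(0.75).

    Consistent for the standard deviation under normality (sMAD of a large
    standard-normal sample tends to 1) but robust to the heavy tails that the
    pathological channels themselves create.
    """
    v = np.asarray(v, dtype=np.float64)
    if np.unique(v).size < 2:
        raise ValueError("sMAD requires at least 2 distinct values")
    return float(np.median(np.abs(v - np.median(v))) / MAD_TO_SD)


def patient_equal_weights(
    patients: np.ndarray, scale: str = "mean_one"
) -> np.ndarray:
    """Observation weights giving every patient equal total influence.

    Each channel of patient ``p`` receives weight proportional to
    ``1 / n_channels(p)``.  ``scale`` fixes the overall normalisation:

    - ``"mean_one"`` (default): weights average to 1 (sum = n_channels), so a
      balanced cohort reduces exactly to the unweighted fit and Wald inference
      keeps its nominal calibration;
    - ``"patient_sum_one"``: each patient's channels sum to 1
      (sum = n_patients), a per-patient-observation scale under which Wald
      standard errors are conservative when channels outnumber patients.

    The scale only affects standard errors/p-values, not point estimates.
    """
    patients = np.asarray(patients)
    counts = pd.Series(patients).map(pd.Series(patients).value_counts())
    w = 1.0 / counts.to_numpy(dtype=np.float64)
    if scale == "mean_one":
        w *= len(w) / w.sum()
    elif scale == "patient_sum_one":
        pass
    else:
        raise ValueError("scale must be 'mean_one' or 'patient_sum_one'")
    return w


def bonferroni_tier(p: float, n_tests: int = DEFAULT_N_TESTS) -> int:
    """Significance tier 0-4: number of thresholds {.05,.01,.001,.0001}/n passed."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not np.isfinite(p):
        return 0
    return int(sum(p < a / n_tests for a in TIER_ALPHAS))


@dataclass
class FeatureAssociation:
    """Per-feature logistic association model.

    Parameters
    ----------
    features : pandas.DataFrame
        One row per channel; feature columns only (e.g. ``band1_f1``..).
    labels : array-like of {0, 1}
        Binary channel label (SOZ / RV / temporal lobe membership).
    patients : array-like
        Patient identifier per channel, for equal-patient weighting.
    label_name : str
        Name recorded in the results (e.g. ``"SOZ"``).
    weight_scale : str
        Normalisation of the patient-equal weights (see
        :func:`patient_equal_weights`).
    """

    features: pd.DataFrame
    labels: np.ndarray
    patients: np.ndarray
    label_name: str = "SOZ"
    weight_scale: str = "mean_one"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.float64)
        self.patients = np.asarray(self.patients)
        if len(self.features) != len(self.labels) or len(self.labels) != len(
            self.patients
        ):
            raise ValueError("features, labels and patients must align")
        if np.unique(self.patients).size < 2:
            raise ValueError("need >= 2 patients")
        if set(np.unique(self.labels)) != {0.0, 1.0}:
            raise ValueError("both label classes must be present")

    def fit(self, n_tests: int = DEFAULT_N_TESTS) -> "AssociationResults":
        w = patient_equal_weights(self.patients, self.weight_scale)
        rows = []
        for col in self.features.columns:
            v = self.features[col].to_numpy(dtype=np.float64)
            rows.append(self._fit_one(col, v, w, n_tests))
        table = pd.DataFrame(rows)
        return AssociationResults(
            table=table,
            label_name=self.label_name,
            n_tests=n_tests,
            weight_scale=self.weight_scale,
            n_channels=len(self.labels),
            n_patients=int(np.unique(self.patients).size),
            features=self.features,
        )

    def _fit_one(self, name: str, v: np.ndarray, w: np.ndarray, n_tests: int) -> dict:
        base = {
            "feature": name,
            "label": self.label_name,
            "n_channels": len(v),
            "n_patients": int(np.unique(self.patients).size),
        }
        keep = np.isfinite(v)
        v, y, wk = v[keep], self.labels[keep], w[keep]
        try:
            scale = smad(v)
        except ValueError:
            warnings.warn(f"feature {name}: sMAD undefined; skipped")
            return {**base, "or": np.nan, "ci_lo": np.nan, "ci_hi": np.nan,
                    "p": np.nan, "tier": 0, "separated": False, "smad": np.nan}
        x = v / scale
        X = sm.add_constant(x)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(
                    y, X, family=sm.families.Binomial(), var_weights=wk
                ).fit()
            beta = res.params[1]
            se = res.bse[1]
            separated = not np.isfinite(se) or abs(beta) > 30
        except Exception:
            separated = True
        if separated:
            warnings.warn(f"feature {name}: separation; odds ratio unbounded")
            return {**base, "or": np.inf, "ci_lo": np.nan, "ci_hi": np.nan,
                    "p": np.nan, "tier": 0, "separated": True, "smad": scale}
        z = norm.ppf(0.975)
        p = res.pvalues[1]
        return {
            **base,
            "or": float(np.exp(beta)),
            "ci_lo": float(np.exp(beta - z * se)),
            "ci_hi": float(np.exp(beta + z * se)),
            "p": float(p),
            "tier": bonferroni_tier(float(p), n_tests),
            "separated": False,
            "smad": scale,
        }


@dataclass
class AssociationResults:
    """Fitted per-feature odds ratios with Wald CIs and Bonferroni tiers."""

    table: pd.DataFrame
    label_name: str
    n_tests: int
    weight_scale: str
    n_channels: int
    n_patients: int
    features: pd.DataFrame = field(repr=False, default=None)

    def correlation_matrix(self) -> pd.DataFrame:
        """Pearson correlation between features, pooled across patients."""
        return self.features.corr(method="pearson")

    def summary(self) -> str:
        stars = {i: "*" * i for i in range(5)}
        lines = [
            f"Feature association with {self.label_name} "
            f"({self.n_channels} channels, {self.n_patients} patients; "
            f"Bonferroni n={self.n_tests}, weights={self.weight_scale})",
            f"{'feature':<12}{'OR/sMAD':>9}{'95% CI':>19}{'p':>11}  sig",
        ]
        for _, r in self.table.iterrows():
            if not np.isfinite(r["or"]):
                lines.append(f"{r['feature']:<12}{'(separated)':>9}")
                continue
            ci = f"[{r['ci_lo']:.2f}, {r['ci_hi']:.2f}]"
            lines.append(
                f"{r['feature']:<12}{r['or']:>9.3f}{ci:>19}{r['p']:>11.2e}"
                f"  {stars[int(r['tier'])]}"
            )
        return "\n".join(lines)

    def plot(self, ax=None):
        """Forest-style odds-ratio plot (log scale, CI whiskers)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 0.22 * len(self.table) + 1))
        t = self.table[np.isfinite(self.table["or"])]
        ypos = np.arange(len(t))
        ax.errorbar(
            t["or"], ypos,
            xerr=[t["or"] - t["ci_lo"], t["ci_hi"] - t["or"]],
            fmt="o", ms=3, lw=1, color="k",
        )
        ax.axvline(1.0, color="0.6", lw=0.8)
        ax.set_xscale("log")
        ax.set_yticks(ypos)
        ax.set_yticklabels(t["feature"], fontsize=6)
        ax.set_xlabel("odds ratio per sMAD")
        ax.set_title(self.label_name)
        return ax
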