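"""Condition-level inference models for MEA firing rates and amplitudes.

Three model classes, each following the fit-then-results idiom: a model
is constructed from a long-format DataFrame, ``fit()`` returns a
results object carrying estimates, Wald standard errors and a
``summary()`` table.

* :class:`GammaFrequencyGLM` — spike-cluster firing frequencies (Hz)
  are positive and right-skewed; they are modelled with a
  Gamma-family GLM with the inverse (canonical) link on interacting
  categorical treatment x recording effects.  Fitted cell means are
  reported on the Hz scale with delta-method SEs.
* :class:`AmplitudeMixedModel` — log10 waveform amplitude (uV) with
  treatment x recording fixed effects and nested random intercepts
  for experiment / electrode / spike cluster, fitted by REML.
* :class:`FrequencyMixedModel` — array-level log10 firing rate with
  treatment x recording fixed effects and a random experiment
  intercept.

Zero-frequency clusters are excluded from the Gamma fit (the Gamma
distribution has positive support); an optional ``(n+1)/duration``
offset mode retains them.  Multiplicity-adjusted contrasts use the
single-step method: the joint normal distribution of all contrast
statistics, with correlation taken from the fit covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from patsy import build_design_matrices

_FORMULA = "{y} ~ C(treatment) * C(recording)"


@dataclass
class ContrastResult:
    contrast: str
    estimate: float
    se: float
    statistic: float
    p_raw: float
    p_adjusted: float
    method: str


def _cell_frame(treatments, recordings) -> pd.DataFrame:
    cells = [(t, r) for t in treatments for r in recordings]
    return pd.DataFrame(cells, columns=["treatment", "recording"])


class GammaFrequencyGLM:
    """Gamma GLM (inverse link) for cluster firing frequencies.

    Parameters
    ----------
    data : DataFrame with columns ``hz``, ``treatment``, ``recording``.
        All frequencies must be strictly positive unless
        ``zero_offset`` supplies the pseudocount duration for the
        (n+1)/duration transform.
    """

    def __init__(self, data: pd.DataFrame, zero_offset_duration: float | None = None):
        df = data.copy()
        required = {"hz", "treatment", "recording"}
        if missing := required - set(df.columns):
            raise ValueError(f"missing column(s): {sorted(missing)}")
        if zero_offset_duration is not None:
            df["hz"] = df["hz"] + 1.0 / zero_offset_duration
        bad = df.index[df["hz"] <= 0].tolist()
        if bad:
            raise ValueError(f"non-positive frequencies at rows {bad[:10]} (Gamma support is positive)")
        counts = df.groupby(["treatment", "recording"], observed=True).size()
        if (counts < 2).any():
            raise ValueError("every treatment x recording cell needs >= 2 observations")
        if df["hz"].std() == 0:
            raise ValueError("constant response: Gamma dispersion degenerate")
        self.data = df

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kw) -> "GammaFrequencyGLM":
        return cls(data, **kw)

    def fit(self) -> "GammaFrequencyResults":
        with warnings.catch_warnings():
            # the inverse link is the Gamma family's canonical choice here;
            # statsmodels warns that it can leave the positive domain during
            # iteration (we surface non-convergence instead)
            warnings.simplefilter("ignore")
            model = smf.glm(
                _FORMULA.format(y="hz"),
                data=self.data,
                family=sm.families.Gamma(sm.families.links.InversePower()),
            )
            res = model.fit()
        if not res.converged:
            raise RuntimeError("Gamma GLM did not converge")
        return GammaFrequencyResults(self, res)


class GammaFrequencyResults:
    """Fitted Gamma GLM with per-cell mean frequencies on the Hz scale."""

    def __init__(self, model: GammaFrequencyGLM, res):
        self.model = model
        self._res = res
        self.params = res.params
        self.cov_params = res.cov_params()
        df = model.data
        cells = _cell_frame(sorted(df["treatment"].unique()), sorted(df["recording"].unique()))
        pred = res.get_prediction(cells)
        sf = pred.summary_frame()
        self.mu_by_cell = cells.assign(
            mu_hz=sf["mean"].to_numpy(), se=sf["mean_se"].to_numpy()
        )
        sizes = df.groupby(["treatment", "recording"], observed=True).size()
        self.n_by_cell = cells.assign(
            n=[sizes.loc[(t, r)] for t, r in cells.itertuples(index=False)]
        )

    def cell_contrast(self, cell_a: tuple[str, str], cell_b: tuple[str, str]) -> np.ndarray:
        """Linear-predictor contrast row for cell_a - cell_b."""
        di = self._res.model.data.design_info
        a = np.asarray(
            build_design_matrices([di], pd.DataFrame([{"treatment": cell_a[0], "recording": cell_a[1]}]))[0]
        )[0]
        b = np.asarray(
            build_design_matrices([di], pd.DataFrame([{"treatment": cell_b[0], "recording": cell_b[1]}]))[0]
        )[0]
        return a - b

    def summary(self):
        return self._res.summary()


def _nested_keys(df: pd.DataFrame) -> pd.DataFrame:
    """Make electrode/cluster labels unique within their parent grouping."""
    out = df.copy()
    out["electrode_key"] = out["experiment"].astype(str) + "/" + out["electrode"].astype(str)
    out["cluster_key"] = out["electrode_key"] + "/" + out["cluster"].astype(str)
    return out


class _BaseMixed:
    response: str
    formula: str

    def _treatment_changes(self, res, data: pd.DataFrame) -> pd.DataFrame:
        """Post-minus-pre change per treatment, with Wald SE."""
        di = res.model.data.design_info
        k = len(res.fe_params)
        cov = np.asarray(res.cov_params())[:k, :k]
        recs = sorted(data["recording"].unique())
        pre, post = recs[0], recs[-1]
        rows = []
        for t in sorted(data["treatment"].unique()):
            (m_post,) = build_design_matrices([di], pd.DataFrame([{"treatment": t, "recording": post}]))
            (m_pre,) = build_design_matrices([di], pd.DataFrame([{"treatment": t, "recording": pre}]))
            c = np.asarray(m_post)[0] - np.asarray(m_pre)[0]
            est = float(c @ res.fe_params)
            se = float(np.sqrt(c @ cov @ c))
            rows.append({"treatment": t, "delta": est, "se": se})
        return pd.DataFrame(rows)


class AmplitudeMixedModel(_BaseMixed):
    """REML mixed model for log10 waveform amplitude.

    Fixed effects: treatment x recording (interacting categoricals).
    Random intercepts: experiment, electrode within experiment, and
    spike cluster within electrode (nested).  Input should be
    pre-filtered to persistent clusters with baseline amplitude at or
    above the reporting floor (see :func:`persistent_amplitude_filter`).
    """

    def __init__(self, data: pd.DataFrame):
        required = {"log10_uv", "treatment", "recording", "cluster", "electrode", "experiment"}
        if missing := required - set(data.columns):
            raise ValueError(f"missing column(s): {sorted(missing)}")
        self.data = _nested_keys(data)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame) -> "AmplitudeMixedModel":
        return cls(data)

    def fit(self, drop_innermost_on_singular: bool = True) -> "MixedModelResults":
        vc = {
            "electrode": "0 + C(electrode_key)",
            "cluster": "0 + C(cluster_key)",
        }
        data = self.data
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(
                _FORMULA.format(y="log10_uv"),
                data,
                groups=data["experiment"],
                re_formula="1",
                vc_formula=vc,
            )
            res = model.fit(reml=True)
            dropped = None
            if drop_innermost_on_singular and not _vc_ok(res):
                vc2 = {"electrode": vc["electrode"]}
                model = smf.mixedlm(
                    _FORMULA.format(y="log10_uv"),
                    data,
                    groups=data["experiment"],
                    re_formula="1",
                    vc_formula=vc2,
                )
                res = model.fit(reml=True)
                dropped = "cluster"
        return MixedModelResults(self, res, "log10_amplitude", data, dropped_component=dropped)


class FrequencyMixedModel(_BaseMixed):
    """REML mixed model for array-level log10 firing rate.

    Fixed treatment x recording effects with a random experiment
    intercept.  With a single experiment the random effect is
    unidentifiable; the model falls back to ordinary least squares with
    a warning.
    """

    def __init__(self, data: pd.DataFrame):
        required = {"log10_hz", "treatment", "recording", "experiment"}
        if missing := required - set(data.columns):
            raise ValueError(f"missing column(s): {sorted(missing)}")
        self.data = data.copy()

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame) -> "FrequencyMixedModel":
        return cls(data)

    def fit(self) -> "MixedModelResults":
        data = self.data
        if data["experiment"].nunique() < 2:
            warnings.warn("single experiment: falling back to a fixed-effects model", stacklevel=2)
            res = smf.ols(_FORMULA.format(y="log10_hz"), data).fit()
            return MixedModelResults(self, res, "log10_mfr", data, fixed_only=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(
                _FORMULA.format(y="log10_hz"),
                data,
                groups=data["experiment"],
            )
            res = model.fit(reml=True)
        return MixedModelResults(self, res, "log10_mfr", data)


class MixedModelResults:
    """Fitted mixed (or fallback fixed) model with treatment-change table."""

    def __init__(self, model, res, response: str, data: pd.DataFrame,
                 fixed_only: bool = False, dropped_component: str | None = None):
        self.model = model
        self._res = res
        self.response = response
        self.fixed_only = fixed_only
        self.dropped_component = dropped_component
        if fixed_only:
            self.fe_params = res.params
            self.cov_fe = np.asarray(res.cov_params())
            self.variance_components = {}
        else:
            self.fe_params = res.fe_params
            k = len(res.fe_params)
            self.cov_fe = np.asarray(res.cov_params())[:k, :k]
            self.variance_components = _variance_components(res)
        di = res.model.data.design_info
        self._design_info = di
        self.treatment_changes = _BaseMixed._treatment_changes(self, res if not fixed_only else _OLSShim(res), data)

    def summary(self):
        return self._res.summary()


class _OLSShim:
    """Give an OLS result the fe_params/cov_params surface of MixedLM."""

    def __init__(self, res):
        self._res = res
        self.fe_params = res.params
        self.model = res.model

    def cov_params(self):
        return self._res.cov_params()


def _vc_ok(res) -> bool:
    try:
        vcs = res.vcomp
    except AttributeError:
        return True
    return bool(np.all(np.isfinite(vcs))) and res.converged


def _variance_components(res) -> dict[str, float]:
    out = {"experiment": float(res.cov_re.iloc[0, 0]) if res.cov_re.size else np.nan}
    names = getattr(res.model, "exog_vc", None)
    if res.vcomp.size:
        labels = res.model.exog_vc.names if names is not None else [f"vc{i}" for i in range(res.vcomp.size)]
        for lab, v in zip(labels, res.vcomp):
            out[lab] = float(v)
    out["residual"] = float(res.scale)
    return out


# ---------------------------------------------------------------------------
# input filter for the amplitude model

def persistent_amplitude_filter(
    cluster_table: pd.DataFrame,
    min_amplitude_uv: float = 30.0,
    pre_recording: str | None = None,
) -> pd.DataFrame:
    """Restrict amplitude observations to analysable clusters.

    Keeps clusters whose amplitude in the pre-treatment recording is at
    least ``min_amplitude_uv`` and which are active in every modelled
    recording (the persistent paradigm) — amplitude is a
    frequency-independent phenotype, measurable only where the cluster
    fired.  Expects one row per cluster x recording with columns
    ``cluster``, ``recording``, ``amplitude_uv``.
    """
    df = cluster_table
    recs = list(pd.unique(df["recording"]))
    pre = pre_recording if pre_recording is not None else recs[0]
    per_cluster = df.groupby("cluster", observed=True)
    keep = []
    for cid, sub in per_cluster:
        if set(recs) - set(sub["recording"]):
            continue  # not persistent
        pre_amp = sub.loc[sub["recording"] == pre, "amplitude_uv"]
        if pre_amp.empty or pre_amp.iloc[0] < min_amplitude_uv:
            continue
        keep.append(cid)
    return df[df["cluster"].isin(keep)].copy()


# ---------------------------------------------------------------------------
# multiplicity-adjusted contrasts

def contrast_tests(
    results,
    contrasts: dict[str, np.ndarray],
    method: str = "single_step",
    n_draws: int = 100_000,
    seed: int = 0,
) -> list[ContrastResult]:
    """General linear hypothesis tests with multiplicity adjustment.

    ``contrasts`` maps labels to coefficient-space contrast rows
    (matching the fit's parameter vector).  The single-step method
    adjusts each p against the joint normal distribution of all
    contrast z statistics, using the correlation implied by the fit
    covariance (seeded Monte-Carlo integration); ``bonferroni`` and
    ``none`` are also available.  Adjusted p is never below raw p.
    """
    if method not in {"single_step", "bonferroni", "none"}:
        raise ValueError(f"unknown method {method!r}")
    if hasattr(results, "fe_params"):
        beta = np.asarray(results.fe_params)
        cov = np.asarray(results.cov_fe)
    else:
        beta = np.asarray(results.params)
        cov = np.asarray(results.cov_params)
    labels = list(contrasts)
    cmat = np.stack([np.asarray(contrasts[k], dtype=float) for k in labels])
    if cmat.shape[1] != beta.size:
        raise ValueError(
            f"contrast length {cmat.shape[1]} does not match {beta.size} parameters"
        )
    est = cmat @ beta
    vcov = cmat @ cov @ cmat.T
    se = np.sqrt(np.diag(vcov))
    if np.any(se == 0):
        bad = [labels[i] for i in np.flatnonzero(se == 0)]
        raise ValueError(f"inestimable contrast(s): {bad}")
    z = est / se
    from scipy.stats import norm

    p_raw = 2.0 * norm.sf(np.abs(z))
    m = len(labels)
    if method == "none" or m == 1:
        p_adj = p_raw.copy()
    elif method == "bonferroni":
        p_adj = np.minimum(1.0, m * p_raw)
    else:
        corr = vcov / np.outer(se, se)
        rng = np.random.default_rng(seed)
        # max-|Z| reference distribution under the joint null
        l = np.linalg.cholesky(corr + 1e-12 * np.eye(m))
        draws = rng.standard_normal((n_draws, m)) @ l.T
        maxabs = np.abs(draws).max(axis=1)
        p_adj = np.array([np.mean(maxabs >= abs(zi)) for zi in z])
    p_adj = np.minimum(1.0, np.maximum(p_adj, p_raw))
    return [
        ContrastResult(
            contrast=labels[i],
            estimate=float(est[i]),
            se=float(se[i]),
            statistic=float(z[i]),
            p_raw=float(p_raw[i]),
            p_adjusted=float(p_adj[i]),
            method=method,
        )
        for i in range(m)
    ]
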