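"""Posterior summaries: risk surfaces, hotspot probabilities, variance
decompositions and scaling-parameter reports.

Every functional of the parameters (exponentials, products, variance
fractions) is computed per retained draw and then summarized across draws,
never by plugging posterior means into the functional — this avoids the
Jensen-gap bias of means-of-nonlinear vs nonlinear-of-means.

Three risk surfaces are reported per area i:

* shared risk exp(theta_i), common to both outcomes;
* specific risk exp(s_ik + u_ik) for outcome k;
* combined relative risk r_ik = exp(alpha_k + c_k theta_i + s_ik + u_ik).

Hotspots are probabilistic: the exceedance probability
Pr(exp(theta_i) > 1 | data) (and the specific-risk analogue) is estimated by
the fraction of retained draws exceeding one, then binned into probability
classes for mapping (top class 0.96-1.00 by default).

The variance decomposition splits, per draw and per outcome, the across-area
empirical variance of the log relative risk into the scaled shared part
Var(c_k theta), the structured specific part Var(s_k) and the unstructured
part Var(u_k); the three fractions sum to one by construction. The combined
specific variance Var(s_k + u_k) is reported alongside, since it differs
from Var(s_k) + Var(u_k) in finite samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mcmc_sampler import PosteriorSamples

_CI = (2.5, 97.5)


def _summ(draws: np.ndarray, axis: int = 0) -> dict:
    return {
        "mean": np.mean(draws, axis=axis),
        "lo": np.percentile(draws, _CI[0], axis=axis),
        "hi": np.percentile(draws, _CI[1], axis=axis),
    }


# ---------------------------------------------------------------------------
# Risk surfaces
# ---------------------------------------------------------------------------

@dataclass
class RiskSurfaces:
    """Per-area posterior summaries of the three risk surfaces.

    Each ``*_mean`` / ``*_lo`` / ``*_hi`` is an (n,) or (2, n) array;
    exceedance probabilities are the posterior probabilities that the
    exponentiated component exceeds 1.
    """

    area_ids: list
    shared_mean: np.ndarray
    shared_lo: np.ndarray
    shared_hi: np.ndarray
    shared_exceed: np.ndarray
    specific_mean: np.ndarray    # (2, n)
    specific_lo: np.ndarray
    specific_hi: np.ndarray
    specific_exceed: np.ndarray  # (2, n)
    combined_mean: np.ndarray    # (2, n)
    combined_lo: np.ndarray
    combined_hi: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"area_id": self.area_ids})
        df["shared_risk"] = self.shared_mean
        df["shared_risk_lo"] = self.shared_lo
        df["shared_risk_hi"] = self.shared_hi
        df["pr_shared_gt1"] = self.shared_exceed
        for k in (1, 2):
            df[f"specific_risk_{k}"] = self.specific_mean[k - 1]
            df[f"specific_risk_{k}_lo"] = self.specific_lo[k - 1]
            df[f"specific_risk_{k}_hi"] = self.specific_hi[k - 1]
            df[f"pr_specific_{k}_gt1"] = self.specific_exceed[k - 1]
            df[f"combined_risk_{k}"] = self.combined_mean[k - 1]
            df[f"combined_risk_{k}_lo"] = self.combined_lo[k - 1]
            df[f"combined_risk_{k}_hi"] = self.combined_hi[k - 1]
        return df


def summarize_surfaces(samples: PosteriorSamples) -> RiskSurfaces:
    """Posterior means, 95% intervals and exceedance probabilities of the
    shared, specific and combined risk surfaces, pooled over chains."""
    theta = samples.pooled("theta")          # (d, n)
    s = samples.pooled("s")                  # (d, 2, n)
    u = samples.pooled("u")
    alpha = samples.pooled("alpha")          # (d, 2)
    delta = np.exp(samples.pooled("log_delta"))  # (d,)
    if theta.size == 0:
        raise ValueError("no retained draws")

    shared = np.exp(theta)
    spec = np.exp(s + u)                     # (d, 2, n)
    scal = np.stack([delta, 1.0 / delta], axis=1)          # (d, 2)
    combined = np.exp(alpha[:, :, None] + scal[:, :, None] * theta[:, None, :]
                      + s + u)

    sh = _summ(shared)
    sp = _summ(spec)
    cb = _summ(combined)
    return RiskSurfaces(
        area_ids=list(samples.area_ids),
        shared_mean=sh["mean"], shared_lo=sh["lo"], shared_hi=sh["hi"],
        shared_exceed=np.mean(shared > 1.0, axis=0),
        specific_mean=sp["mean"],
        specific_lo=sp["lo"], specific_hi=sp["hi"],
        specific_exceed=np.mean(spec > 1.0, axis=0),
        combined_mean=cb["mean"], combined_lo=cb["lo"], combined_hi=cb["hi"],
    )


# ---------------------------------------------------------------------------
# Variance decomposition
# ---------------------------------------------------------------------------

@dataclass
class VarianceDecomposition:
    """Per-outcome posterior summaries (mean, 2.5%, 97.5%) of the empirical
    variances and variance fractions, plus the per-draw fraction arrays used
    by coverage studies.

    Keys of ``table``: rows are quantities (var_shared, var_structured,
    var_unstructured, var_specific_combined, frac_shared, frac_structured,
    frac_unstructured), columns outcome_1 / outcome_2 with mean and CI.
    """

    table: pd.DataFrame
    frac_shared_draws: np.ndarray        # (d, 2)
    frac_structured_draws: np.ndarray
    frac_unstructured_draws: np.ndarray

    def fraction_interval(self, which: str, k: int) -> tuple:
        draws = {"shared": self.frac_shared_draws,
                 "structured": self.frac_structured_draws,
                 "unstructured": self.frac_unstructured_draws}[which][:, k - 1]
        return (float(np.percentile(draws, _CI[0])),
                float(np.percentile(draws, _CI[1])))


def _empirical_var(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Across-area sample variance (ddof=1), the 'empirical variance' of a
    realized field."""
    return np.var(x, axis=axis, ddof=1)


def variance_decomposition(samples: PosteriorSamples) -> VarianceDecomposition:
    theta = samples.pooled("theta")
    if theta.shape[1] < 2:
        raise ValueError("variance decomposition needs at least 2 areas")
    s = samples.pooled("s")
    u = samples.pooled("u")
    delta = np.exp(samples.pooled("log_delta"))
    scal = np.stack([delta, 1.0 / delta], axis=1)            # (d, 2)

    var_shared = _empirical_var(scal[:, :, None] * theta[:, None, :])  # (d, 2)
    var_s = _empirical_var(s)
    var_u = _empirical_var(u)
    var_su = _empirical_var(s + u)
    total = var_shared + var_s + var_u
    frac_shared = var_shared / total
    frac_struct = var_s / total
    frac_unstruct = var_u / total

    rows = []
    quantities = [
        ("var_shared", var_shared),
        ("var_structured", var_s),
        ("var_unstructured", var_u),
        ("var_specific_combined", var_su),
        ("frac_shared", frac_shared),
        ("frac_structured", frac_struct),
        ("frac_unstructured", frac_unstruct),
    ]
    for name, draws in quantities:
        st = _summ(draws)
        for k in (1, 2):
            rows.append({
                "quantity": name, "outcome": k,
                "mean": float(st["mean"][k - 1]),
                "lo": float(st["lo"][k - 1]),
                "hi": float(st["hi"][k - 1]),
            })
    return VarianceDecomposition(
        table=pd.DataFrame(rows),
        frac_shared_draws=frac_shared,
        frac_structured_draws=frac_struct,
        frac_unstructured_draws=frac_unstruct,
    )


def shared_fraction_from_variances(var_shared, var_structured, var_unstructured) -> float:
    """Var(scaled shared) / total, from plug-in (e.g. posterior-mean)
    empirical variances."""
    total = var_shared + var_structured + var_unstructured
    if total <= 0:
        raise ValueError("variances sum to zero")
    if min(var_shared, var_structured, var_unstructured) < 0:
        raise ValueError("variances must be non-negative")
    return float(var_shared / total)


def structured_fraction_from_variances(var_shared, var_structured, var_unstructured) -> float:
    """Var(s_k) / (Var(scaled shared) + Var(s_k) + Var(u_k))."""
    return shared_fraction_from_variances(var_structured, var_shared, var_unstructured)


def unstructured_fraction_from_variances(var_shared, var_structured, var_unstructured) -> float:
    return shared_fraction_from_variances(var_unstructured, var_structured, var_shared)


# ---------------------------------------------------------------------------
# Scaling parameter
# ---------------------------------------------------------------------------

def scaling_summary(samples: PosteriorSamples) -> dict:
    """Posterior report on the scaling parameter.

    ``delta`` and ``inv_delta`` are summarized from their own draws (the
    mean of 1/delta is not 1/mean(delta)). ``gradient_ratio`` is the ratio of
    the two posterior means, matching the headline arithmetic of reports that
    quote mean(delta)/mean(1/delta); ``gradient_ratio_per_draw`` is the
    posterior mean of delta^2, the per-draw version of the same quantity.
    """
    delta = np.exp(samples.pooled("log_delta"))
    inv = 1.0 / delta
    d = _summ(delta)
    i = _summ(inv)
    r2 = _summ(delta ** 2)
    return {
        "delta": {k: float(v) for k, v in d.items()},
        "inv_delta": {k: float(v) for k, v in i.items()},
        "gradient_ratio": float(d["mean"] / i["mean"]),
        "gradient_ratio_per_draw": {k: float(v) for k, v in r2.items()},
        "delta_interval_contains_1": bool(d["lo"] <= 1.0 <= d["hi"]),
    }


# ---------------------------------------------------------------------------
# Hotspot classification
# ---------------------------------------------------------------------------

DEFAULT_CLASS_EDGES = (0.2, 0.4, 0.6, 0.8, 0.96)


def classify_hotspots(probabilities: np.ndarray,
                      class_edges=DEFAULT_CLASS_EDGES) -> tuple:
    """Bin exceedance probabilities into map classes.

    ``class_edges`` are the interior boundaries; bins are half-open
    [lo, hi) with the top bin closed at 1.0, so a probability exactly at an
    interior edge falls in the upper bin. Returns (class_index, labels).
    """
    p = np.asarray(probabilities, dtype=float)
    edges = np.asarray(class_edges, dtype=float)
    if np.any((edges <= 0) | (edges >= 1)) or np.any(np.diff(edges) <= 0):
        raise ValueError("class edges must be strictly increasing and inside (0, 1)")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    idx = np.digitize(p, edges, right=False)
    bounds = [0.0, *edges.tolist(), 1.0]
    labels = [f"[{bounds[i]:g}, {bounds[i + 1]:g})" for i in range(len(bounds) - 2)]
    labels.append(f"[{bounds[-2]:g}, 1]")
    return idx, labels
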