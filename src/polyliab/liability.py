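"""Liability-threshold-model calculus.

Liability is modelled as standard normal in the population; diagnosis
occurs when liability exceeds the threshold t = Phi^-1(1 - K) set by the
population prevalence K. Under this model the mean liability of affected
subjects is the truncated-normal mean phi(t)/K and that of unaffected
subjects is -phi(t)/(1-K). A rare-variant class with a rho-fold excess
risk corresponds to a mean-liability shift delta such that
Normal(delta, 1) exceeds t with the carrier-specific risk.

Two parametrizations of "rho-fold risk" are supported and named
explicitly: ``risk_ratio`` (carrier risk = rho * K) and ``odds_ratio``
(carrier odds = rho * K/(1-K)). At K = 0.015 and rho = 15 these imply
delta = 1.415 and delta = 1.277 respectively; reports surface both.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import norm

RISK_SCALES = ("risk_ratio", "odds_ratio")


def threshold_from_prevalence(prevalence: float) -> float:
    """Diagnostic threshold t = Phi^-1(1 - K) on the liability scale."""
    if not 0 < prevalence < 1:
        raise ValueError(f"prevalence must be in (0, 1), got {prevalence}")
    return float(norm.isf(prevalence))


def group_means(prevalence: float) -> tuple[float, float]:
    """Mean liability of affected and unaffected subjects.

    Truncated standard normal means above/below t: (phi(t)/K, -phi(t)/(1-K)).
    """
    t = threshold_from_prevalence(prevalence)
    dens = norm.pdf(t)
    return float(dens / prevalence), float(-dens / (1.0 - prevalence))


def carrier_risk(prevalence: float, rho: float, risk_scale: str = "odds_ratio") -> float:
    """Disease risk of carriers under a rho-fold excess on the chosen scale."""
    if rho <= 0:
        raise ValueError(f"risk ratio must be positive, got {rho}")
    if risk_scale not in RISK_SCALES:
        raise ValueError(f"risk_scale must be one of {RISK_SCALES}, got {risk_scale!r}")
    if not 0 < prevalence < 1:
        raise ValueError(f"prevalence must be in (0, 1), got {prevalence}")
    if risk_scale == "risk_ratio":
        k_c = rho * prevalence
    else:
        omega = prevalence / (1.0 - prevalence)
        k_c = rho * omega / (1.0 + rho * omega)
    if k_c >= 1:
        raise ValueError(
            f"carrier risk {k_c:.3f} >= 1 (prevalence {prevalence}, rho {rho}, {risk_scale})"
        )
    return float(k_c)


def carrier_shift(prevalence: float, rho: float, risk_scale: str = "odds_ratio") -> float:
    """Mean-liability shift delta of carriers implied by a rho-fold risk.

    delta = t - Phi^-1(1 - K_c): the displacement of a unit-variance normal
    whose mass above t equals the carrier risk K_c.
    """
    t = threshold_from_prevalence(prevalence)
    k_c = carrier_risk(prevalence, rho, risk_scale)
    return float(t - norm.isf(k_c))


def half_distance(prevalence: float) -> float:
    """Half the distance between affected and unaffected mean liabilities."""
    mean_aff, mean_unaff = group_means(prevalence)
    return (mean_aff - mean_unaff) / 2.0


@dataclass
class LiabilityModel:
    """Derived quantities of the threshold model at one (K, rho) setting."""

    prevalence: float
    risk_ratio: float
    risk_scale: str = "odds_ratio"

    def __post_init__(self) -> None:
        self.threshold = threshold_from_prevalence(self.prevalence)
        self.mean_affected, self.mean_unaffected = group_means(self.prevalence)
        self.carrier_risk = carrier_risk(self.prevalence, self.risk_ratio, self.risk_scale)
        self.carrier_shift = carrier_shift(self.prevalence, self.risk_ratio, self.risk_scale)
        self.half_distance = half_distance(self.prevalence)
        self.midpoint = (self.mean_affected + self.mean_unaffected) / 2.0


def additivity_diagnostics(model: LiabilityModel, observed_means: dict[str, float] | None = None) -> dict:
    """Place the carrier shift and observed carrier score on the
    unaffected-to-affected interval.

    ``observed_means`` maps {"affected", "unaffected", "affected_carriers"}
    to the group means of a standardized burden score. The report emits both
    the arithmetic midpoint (a+u)/2 and the half-distance (a-u)/2 convention,
    and the position of delta / the carrier mean as a fraction of the
    interval from the unaffected to the affected mean (0.5 = exactly
    between the two groups).
    """
    a, u = model.mean_affected, model.mean_unaffected
    report = {
        "prevalence": model.prevalence,
        "threshold": model.threshold,
        "mean_affected": a,
        "mean_unaffected": u,
        "midpoint": (a + u) / 2.0,
        "half_distance": (a - u) / 2.0,
        "carrier_shift": model.carrier_shift,
        "risk_scale": model.risk_scale,
        "carrier_shift_position": (model.carrier_shift - u) / (a - u),
    }
    if observed_means is not None:
        required = {"affected", "unaffected", "affected_carriers"}
        missing = required - observed_means.keys()
        if missing:
            raise ValueError(f"observed_means missing groups: {sorted(missing)}")
        oa, ou = observed_means["affected"], observed_means["unaffected"]
        oc = observed_means["affected_carriers"]
        report["observed"] = {
            "affected": oa,
            "unaffected": ou,
            "affected_carriers": oc,
            "midpoint": (oa + ou) / 2.0,
            "half_distance": (oa - ou) / 2.0,
            "carrier_position": (oc - ou) / (oa - ou),
        }
    return report
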