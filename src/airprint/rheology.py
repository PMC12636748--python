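"""Yield-stress rheology of air-printing support baths.

The gel baths used for embedded air printing are Herschel--Bulkley (HB)
yield-stress fluids: below the yield stress ``tau_y`` they behave as soft
solids, above it they flow with a shear-thinning power law,

    tau(gamma_dot) = tau_y + K * gamma_dot**n        (tau > tau_y).

For use inside a continuum flow solver the stress singularity at zero shear
rate is removed with the Papanastasiou exponential regularization, which
replaces the unyielded solid by a very viscous fluid,

    mu(gamma_dot) = K * gamma_dot**(n-1)
                    + tau_y * (1 - exp(-m_reg * gamma_dot)) / gamma_dot.

The regularization time scale ``m_reg`` controls the zero-shear viscosity
plateau ``tau_y * m_reg``; as ``m_reg -> inf`` the ideal HB law is recovered.

This module also provides flow-curve fitting, the two-pass gel-tearing
recovery statistic, the yield-capillary (plastocapillary) number
``Y = tau_y * R / sigma`` that compares the yield stress with the capillary
pressure of a channel of radius ``R``, and the M1/M2/M3 regime taxonomy:
M1 (low yield stress, air collapses to bubbles), M2 (yield stress arrests
surface tension, stable channels), M3 (elasticity dominates, the gel tears
and does not recover).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import least_squares

__all__ = [
    "HerschelBulkleyParams",
    "MaterialFormulation",
    "FlowCurve",
    "TearingTrace",
    "FlowCurveFit",
    "effective_viscosity",
    "shear_stress",
    "fit_flow_curve",
    "synthesize_flow_curve",
    "recovery_percent",
    "yield_capillary_number",
    "classify_regime",
    "default_catalog",
    "load_catalog",
    "save_catalog",
    "read_flow_curve_csv",
    "write_flow_curve_csv",
    "read_tearing_trace_csv",
    "write_tearing_trace_csv",
    "DEFAULT_M_REG",
    "DEFAULT_MU_MAX",
    "DEFAULT_Y_CRIT",
    "DEFAULT_RECOVERY_THRESHOLD",
]

# Defaults shared across the package.
DEFAULT_M_REG = 1000.0  # s, Papanastasiou regularization time scale
DEFAULT_MU_MAX = 1.0e6  # Pa*s, cap on the zero-shear divergence for n < 1
DEFAULT_Y_CRIT = 0.1  # plastocapillary stability threshold
DEFAULT_RECOVERY_THRESHOLD = 80.0  # %, below this the gel is M3-like
REFERENCE_SHEAR_RATE = 0.01  # 1/s, catalog reference viscosity shear rate


@dataclass(frozen=True)
class HerschelBulkleyParams:
    """Regularized Herschel--Bulkley constitutive parameters.

    Attributes
    ----------
    tau_y : float
        Yield stress, Pa (>= 0).
    K : float
        Consistency index, Pa*s**n (> 0).
    n : float
        Flow index (> 0); n < 1 is shear thinning, n = 1 with tau_y = 0
        is Newtonian with viscosity K.
    m_reg : float
        Papanastasiou regularization time scale, s (> 0).
    """

    tau_y: float
    K: float
    n: float
    m_reg: float = DEFAULT_M_REG

    def __post_init__(self) -> None:
        if not np.isfinite([self.tau_y, self.K, self.n, self.m_reg]).all():
            raise ValueError("Herschel-Bulkley parameters must be finite")
        if self.tau_y < 0:
            raise ValueError(f"tau_y must be >= 0, got {self.tau_y}")
        if self.K <= 0 or self.n <= 0 or self.m_reg <= 0:
            raise ValueError("K, n and m_reg must be positive")


@dataclass(frozen=True)
class MaterialFormulation:
    """A named gel recipe with its HB parameters and interfacial properties."""

    name: str
    hb: HerschelBulkleyParams
    density: float  # kg/m^3
    surface_tension_vs_air: float  # N/m
    storage_modulus: float | None = None  # Pa
    chemistry: str = ""

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError("density must be positive")
        if self.surface_tension_vs_air <= 0:
            raise ValueError("surface_tension_vs_air must be positive")

    def reference_viscosity(self, mu_max: float = DEFAULT_MU_MAX) -> float:
        """Viscosity at the catalog reference shear rate of 0.01 1/s."""
        return float(
            effective_viscosity(REFERENCE_SHEAR_RATE, self.hb, mu_max=mu_max)
        )


@dataclass(frozen=True)
class FlowCurve:
    """A rheometer flow curve: shear rate vs. stress (or viscosity)."""

    shear_rates: np.ndarray  # 1/s, strictly ascending, positive
    values: np.ndarray  # Pa if kind == "stress", Pa*s if kind == "viscosity"
    kind: str = "stress"

    def __post_init__(self) -> None:
        gd = np.asarray(self.shear_rates, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "shear_rates", gd)
        object.__setattr__(self, "values", vals)
        if self.kind not in ("stress", "viscosity"):
            raise ValueError("kind must be 'stress' or 'viscosity'")
        if gd.ndim != 1 or gd.size < 4:
            raise ValueError("flow curve needs >= 4 points")
        if vals.shape != gd.shape:
            raise ValueError("shear_rates and values must have the same length")
        if not (np.isfinite(gd).all() and np.isfinite(vals).all()):
            raise ValueError("flow curve values must be finite")
        if (gd <= 0).any() or (vals <= 0).any():
            raise ValueError("flow curve values must be positive")
        if (np.diff(gd) <= 0).any():
            raise ValueError("shear rates must be strictly ascending")

    @property
    def stresses(self) -> np.ndarray:
        if self.kind == "stress":
            return self.values
        return self.values * self.shear_rates


@dataclass(frozen=True)
class TearingTrace:
    """Two torque traces of a nozzle dragged twice along the same path."""

    time_first: np.ndarray  # s
    torque_first: np.ndarray  # N*m
    time_second: np.ndarray  # s
    torque_second: np.ndarray  # N*m
    pass_gap: float = 0.0  # s between the two passes

    def __post_init__(self) -> None:
        for label in ("time_first", "torque_first", "time_second", "torque_second"):
            arr = np.asarray(getattr(self, label), dtype=float)
            object.__setattr__(self, label, arr)
            if arr.size == 0:
                raise ValueError(f"{label} must be nonempty")
            if not np.isfinite(arr).all():
                raise ValueError(f"{label} must be finite")
        if (self.torque_first < 0).any() or (self.torque_second < 0).any():
            raise ValueError("torque must be >= 0")


# ---------------------------------------------------------------------------
# Constitutive law
# ---------------------------------------------------------------------------

def effective_viscosity(
    gamma_dot: float | np.ndarray,
    hb: HerschelBulkleyParams,
    mu_max: float = DEFAULT_MU_MAX,
) -> np.ndarray:
    """Papanastasiou-regularized Herschel--Bulkley viscosity.

    mu(gd) = K*gd**(n-1) + tau_y*(1 - exp(-m_reg*gd))/gd, capped at ``mu_max``.
    The gd -> 0 limit of the yield term is ``tau_y * m_reg``; for n < 1 the
    power-law term diverges and is absorbed by the cap.
    """
    gd = np.asarray(gamma_dot, dtype=float)
    if not np.isfinite(gd).all():
        raise ValueError("shear rate must be finite")
    if (gd < 0).any():
        raise ValueError("shear rate must be >= 0")
    out = np.empty_like(gd)
    tiny = gd < 1e-12
    with np.errstate(divide="ignore", over="ignore"):
        gd_safe = np.where(tiny, 1.0, gd)
        power = hb.K * gd_safe ** (hb.n - 1.0)
        yield_term = hb.tau_y * (-np.expm1(-hb.m_reg * gd_safe)) / gd_safe
    out = power + yield_term
    # analytic gd -> 0+ limit: yield term -> tau_y*m_reg; power term capped
    zero_limit = hb.tau_y * hb.m_reg + (hb.K if hb.n == 1.0 else mu_max)
    out = np.where(tiny, zero_limit, out)
    out = np.minimum(out, mu_max)
    return out if out.ndim else float(out)


def shear_stress(
    gamma_dot: float | np.ndarray,
    hb: HerschelBulkleyParams,
    mu_max: float = DEFAULT_MU_MAX,
) -> np.ndarray:
    """Shear stress tau = mu_eff(gd) * gd; tau(0) = 0, continuous."""
    gd = np.asarray(gamma_dot, dtype=float)
    tau = effective_viscosity(np.where(gd == 0, 0.0, gd), hb, mu_max=mu_max) * gd
    return tau if tau.ndim else float(tau)


# ---------------------------------------------------------------------------
# Flow-curve fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FlowCurveFit:
    """Result of fitting an ideal HB law to a flow curve."""

    params: HerschelBulkleyParams
    rms_log_residual: float
    converged: bool
    message: str = ""


def fit_flow_curve(
    curve: FlowCurve, m_reg: float = DEFAULT_M_REG
) -> FlowCurveFit:
    """Fit tau = tau_y + K*gd**n to a flow curve by least squares on log stress.

    Fitting in log space weights decades evenly, which matters because flow
    curves span several decades in both axes. The returned parameters carry
    the supplied ``m_reg`` (fitting cannot identify it: rheometer data never
    resolves the regularized zero-shear plateau).
    """
    gd = curve.shear_rates
    tau = curve.stresses
    log_tau = np.log(tau)

    def resid(p: np.ndarray) -> np.ndarray:
        tau_y, K, n = p
        model = tau_y + K * gd**n
        return np.log(np.maximum(model, 1e-300)) - log_tau

    # initial guess: tau_y from the low-rate plateau, power law from the tail
    tau_y0 = max(float(tau[0]) * 0.5, 1e-9)
    hi = gd.size // 2
    slope, intercept = np.polyfit(np.log(gd[hi:]), np.log(tau[hi:]), 1)
    n0 = float(np.clip(slope, 0.05, 2.0))
    K0 = float(np.exp(intercept))
    res = least_squares(
        resid,
        x0=[tau_y0, K0, n0],
        bounds=([0.0, 1e-12, 0.01], [np.inf, np.inf, 5.0]),
        method="trf",
    )
    rms = float(np.sqrt(np.mean(res.fun**2)))
    converged = bool(res.success) and rms < 0.5
    params = HerschelBulkleyParams(
        tau_y=float(res.x[0]), K=float(res.x[1]), n=float(res.x[2]), m_reg=m_reg
    )
    return FlowCurveFit(
        params=params,
        rms_log_residual=rms,
        converged=converged,
        message=str(res.message),
    )


def synthesize_flow_curve(
    hb: HerschelBulkleyParams,
    shear_rates: np.ndarray,
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
) -> FlowCurve:
    """Generate an ideal HB flow curve, optionally with log-normal noise."""
    gd = np.asarray(shear_rates, dtype=float)
    tau = hb.tau_y + hb.K * gd**hb.n
    if noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        tau = tau * np.exp(rng.normal(0.0, noise_sigma, size=gd.shape))
    return FlowCurve(shear_rates=gd, values=tau, kind="stress")


# ---------------------------------------------------------------------------
# Gel-tearing recovery
# ---------------------------------------------------------------------------

def recovery_percent(trace: TearingTrace) -> float:
    """Recovery (%) from the two-pass gel-tearing test.

    The resisting torque of each pass is summarized by the mean of its final
    50% of samples (the steady drag plateau, robust to start-up transients);
    recovery = 100 * plateau(second) / plateau(first). A well-recovering gel
    resists the second pass as strongly as the first (~100%); a torn gel
    offers much less resistance (~50% and below).
    """

    def plateau(torque: np.ndarray) -> float:
        half = torque[torque.size // 2 :]
        return float(np.mean(half))

    first = plateau(trace.torque_first)
    second = plateau(trace.torque_second)
    scale = float(np.max(trace.torque_first))
    if scale <= 0 or first <= 1e-9 * max(scale, 1.0):
        raise ValueError("first-pass plateau is ~0; recovery undefined")
    return float(np.clip(100.0 * second / first, 0.0, 105.0))


# ---------------------------------------------------------------------------
# Plastocapillary number and regime taxonomy
# ---------------------------------------------------------------------------

def yield_capillary_number(tau_y: float, sigma: float, R: float) -> float:
    """Plastocapillary number Y = tau_y * R / sigma.

    Compares the yield stress with the capillary pressure sigma/R of a
    channel of radius R; Y >> 1 means the bath can hold a non-spherical
    air body against surface tension.
    """
    if not (tau_y > 0 and sigma > 0 and R > 0):
        raise ValueError("tau_y, sigma and R must all be positive")
    return tau_y * R / sigma


def classify_regime(
    mat: MaterialFormulation,
    R: float,
    recovery: float,
    y_crit: float = DEFAULT_Y_CRIT,
    recovery_threshold: float = DEFAULT_RECOVERY_THRESHOLD,
) -> str:
    """Classify a bath as M1 (bubbles), M2 (channels) or M3 (tearing).

    M3 is decided first (poor recovery after nozzle passage: the gel tears
    rather than heals); among recovering gels, the plastocapillary number at
    channel radius R separates bubble-forming (M1) from channel-stable (M2).
    """
    if not 0.0 <= recovery <= 105.0:
        raise ValueError("recovery must be a percentage in [0, 105]")
    if recovery < recovery_threshold:
        return "M3"
    y = yield_capillary_number(
        max(mat.hb.tau_y, 1e-300), mat.surface_tension_vs_air, R
    )
    return "M2" if y >= y_crit else "M1"


# ---------------------------------------------------------------------------
# Materials catalog
# ---------------------------------------------------------------------------

def default_catalog() -> dict[str, MaterialFormulation]:
    """Built-in catalog of representative bath formulations.

    M1 barely yields (air retracts into bubbles), M2 holds channels, M3 is
    elasticity-dominated and tears; M1A..M1D interpolate between M1 and M2.
    Values are representative of gelatin/silicone support baths, not measured
    data.
    """
    sigma = 0.025  # N/m, gel-air surface tension scale
    rho = 1000.0

    def mat(name, tau_y, K, n, G=None, chem="gelatin"):
        return MaterialFormulation(
            name=name,
            hb=HerschelBulkleyParams(tau_y=tau_y, K=K, n=n),
            density=rho,
            surface_tension_vs_air=sigma,
            storage_modulus=G,
            chemistry=chem,
        )

    return {
        # M1 is deliberately thin (low K): the capillary remodeling time
        # mu_eff * d / sigma of a printed feature must be short enough that
        # the bubble-regime dynamics complete within a desk-scale run
        "M1": mat("M1", 2.0, 0.1, 0.50, G=30.0),
        "M1A": mat("M1A", 6.0, 4.0, 0.48, G=80.0),
        "M1B": mat("M1B", 15.0, 7.0, 0.47, G=200.0),
        "M1C": mat("M1C", 35.0, 12.0, 0.46, G=450.0),
        "M1D": mat("M1D", 60.0, 16.0, 0.46, G=800.0),
        "M2": mat("M2", 120.0, 20.0, 0.45, G=1500.0),
        "M3": mat("M3", 500.0, 120.0, 0.40, G=12000.0),
    }


def save_catalog(catalog: dict[str, MaterialFormulation], path: str | Path) -> None:
    payload = {}
    for name, m in catalog.items():
        payload[name] = {
            "tau_y_Pa": m.hb.tau_y,
            "K_Pa_sn": m.hb.K,
            "n": m.hb.n,
            "m_reg_s": m.hb.m_reg,
            "density_kg_m3": m.density,
            "surface_tension_N_m": m.surface_tension_vs_air,
            "storage_modulus_Pa": m.storage_modulus,
            "chemistry": m.chemistry,
        }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_catalog(path: str | Path) -> dict[str, MaterialFormulation]:
    payload = yaml.safe_load(Path(path).read_text())
    catalog: dict[str, MaterialFormulation] = {}
    for name, d in payload.items():
        if name in catalog:
            raise ValueError(f"duplicate material name {name!r}")
        catalog[name] = MaterialFormulation(
            name=name,
            hb=HerschelBulkleyParams(
                tau_y=float(d["tau_y_Pa"]),
                K=float(d["K_Pa_sn"]),
                n=float(d["n"]),
                m_reg=float(d.get("m_reg_s", DEFAULT_M_REG)),
            ),
            density=float(d["density_kg_m3"]),
            surface_tension_vs_air=float(d["surface_tension_N_m"]),
            storage_modulus=(
                None
                if d.get("storage_modulus_Pa") is None
                else float(d["storage_modulus_Pa"])
            ),
            chemistry=str(d.get("chemistry", "")),
        )
    return catalog


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

def write_flow_curve_csv(curve: FlowCurve, path: str | Path) -> None:
    col = "stress_Pa" if curve.kind == "stress" else "viscosity_Pa_s"
    pd.DataFrame(
        {"shear_rate_per_s": curve.shear_rates, col: curve.values}
    ).to_csv(path, index=False)


def read_flow_curve_csv(path: str | Path) -> FlowCurve:
    df = pd.read_csv(path)
    if "shear_rate_per_s" not in df.columns:
        raise ValueError("missing column shear_rate_per_s")
    if "stress_Pa" in df.columns:
        return FlowCurve(df["shear_rate_per_s"].values, df["stress_Pa"].values, "stress")
    if "viscosity_Pa_s" in df.columns:
        return FlowCurve(
            df["shear_rate_per_s"].values, df["viscosity_Pa_s"].values, "viscosity"
        )
    raise ValueError("missing stress_Pa or viscosity_Pa_s column")


def write_tearing_trace_csv(trace: TearingTrace, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "time_s": np.concatenate([trace.time_first, trace.time_second]),
            "torque_Nm": np.concatenate([trace.torque_first, trace.torque_second]),
            "pass": np.concatenate(
                [
                    np.ones(trace.time_first.size, dtype=int),
                    2 * np.ones(trace.time_second.size, dtype=int),
                ]
            ),
        }
    )
    df.to_csv(path, index=False)


def read_tearing_trace_csv(path: str | Path, pass_gap: float = 0.0) -> TearingTrace:
    df = pd.read_csv(path)
    for col in ("time_s", "torque_Nm", "pass"):
        if col not in df.columns:
            raise ValueError(f"missing column {col}")
    first = df[df["pass"] == 1]
    second = df[df["pass"] == 2]
    return TearingTrace(
        time_first=first["time_s"].values,
        torque_first=first["torque_Nm"].values,
        time_second=second["time_s"].values,
        torque_second=second["torque_Nm"].values,
        pass_gap=pass_gap,
    )
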