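"""Isothermal titration calorimetry: binding models, simulation and fitting.

The per-injection heat model is the standard Wiseman construction for one or
two independent classes of sites on the cell macromolecule M titrated with
ligand X:

    Q(tot) = V0 * [M] * sum_j  n_j * dH_j * K_j [X]free / (1 + K_j [X]free)

with [X]free solved from mass balance at the post-injection total
concentrations.  Each injection of volume v displaces cell content, so both
totals carry the cumulative dilution factor (1 - v/V0) per injection, and
the measured heat of injection i is

    dq_i = Q_i - Q_{i-1} + (v_i/V0) * (Q_i + Q_{i-1}) / 2

normalised per mole of injectant.  The macromolecule is accounted on a
dimer basis so that a fitted stoichiometry n reads "duplexes bound per
protein dimer", the convention used for TetR-family repressor/operator
titrations.

Fitting is multi-start damped least squares over (n_j, ln K_j, dH_j); for a
two-site fit the site classes are reported weakest first (K_1 < K_2).
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import optimize

R_KCAL = 1.9872e-3  # gas constant, kcal / (mol K)


@dataclass
class TitrationProtocol:
    """Cell/syringe concentrations (μM), injection volumes (μl), temperature (K)."""

    cell_volume_ul: float = 200.0
    cell_concentration_uM: float = 10.0  # macromolecule (dimer basis)
    syringe_concentration_uM: float = 120.0
    injection_volumes_ul: tuple[float, ...] = (1.5,) * 25
    temperature_K: float = 298.15

    def __post_init__(self) -> None:
        if self.cell_volume_ul <= 0 or self.cell_concentration_uM <= 0:
            raise ValueError("cell volume and concentration must be positive")
        if self.syringe_concentration_uM <= 0:
            raise ValueError("syringe concentration must be positive")
        if not self.injection_volumes_ul or any(v <= 0 for v in self.injection_volumes_ul):
            raise ValueError("injection volumes must be positive")
        if not 273.0 <= self.temperature_K <= 373.0:
            raise ValueError("temperature outside [273, 373] K")

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes_ul)


@dataclass
class SiteClass:
    """One class of binding sites: stoichiometry, association constant, enthalpy."""

    n: float  # sites per macromolecule
    K: float  # association constant, 1/M
    dH: float  # kcal/mol

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError(f"site stoichiometry must be positive, got {self.n}")
        if self.K <= 0:
            raise ValueError(f"association constant must be positive, got {self.K}")

    @property
    def Kd(self) -> float:
        return 1.0 / self.K


@dataclass
class BindingParams:
    """Parameters for a one-site or two-site independent-classes model."""

    sites: tuple[SiteClass, ...]

    def __post_init__(self) -> None:
        if len(self.sites) not in (1, 2):
            raise ValueError("supported models have one or two site classes")

    @property
    def model(self) -> str:
        return "one-site" if len(self.sites) == 1 else "two-site"

    @classmethod
    def one_site(cls, n: float, Kd_M: float, dH: float) -> "BindingParams":
        return cls(sites=(SiteClass(n=n, K=1.0 / Kd_M, dH=dH),))

    @classmethod
    def two_site(
        cls, n1: float, Kd1_M: float, dH1: float, n2: float, Kd2_M: float, dH2: float
    ) -> "BindingParams":
        return cls(
            sites=(
                SiteClass(n=n1, K=1.0 / Kd1_M, dH=dH1),
                SiteClass(n=n2, K=1.0 / Kd2_M, dH=dH2),
            )
        )


@dataclass
class Isotherm:
    """Per-injection heats in kcal per mole of injectant."""

    protocol: TitrationProtocol
    heats: np.ndarray

    def __post_init__(self) -> None:
        self.heats = np.asarray(self.heats, float)
        if len(self.heats) != self.protocol.n_injections:
            raise ValueError(
                f"{len(self.heats)} heats for {self.protocol.n_injections} injections"
            )

    @property
    def molar_ratios(self) -> np.ndarray:
        """Cumulative titrant/macromolecule molar ratio after each injection."""
        m, x = _total_concentrations(self.protocol)
        return x / m


@dataclass
class FittedParameter:
    value: float
    stderr: float | None = None


@dataclass
class BindingFit:
    params: BindingParams
    stderr: dict[str, float | None]
    rss: float
    aicc: float
    converged: bool
    n_starts_converged: int
    temperature_K: float

    def summary(self) -> dict:
        out: dict = {"model": self.params.model, "rss": self.rss, "aicc": self.aicc}
        for i, s in enumerate(self.params.sites, start=1):
            thermo = derive_thermo(BindingParams(sites=(s,)), self.temperature_K)[0]
            out[f"site{i}"] = {
                "n": s.n,
                "Kd_M": s.Kd,
                "dH_kcal_mol": s.dH,
                "dG_kcal_mol": thermo["dG"],
                "dS_cal_mol_K": thermo["dS"] * 1000.0,
            }
        return out


# ---------------------------------------------------------------------------
# forward model


def _total_concentrations(protocol: TitrationProtocol) -> tuple[np.ndarray, np.ndarray]:
    """Post-injection total macromolecule and titrant concentrations (M)."""
    v0 = protocol.cell_volume_ul
    m = protocol.cell_concentration_uM * 1e-6
    x = 0.0
    ms, xs = [], []
    for v in protocol.injection_volumes_ul:
        f = 1.0 - v / v0
        m *= f
        x = x * f + protocol.syringe_concentration_uM * 1e-6 * (v / v0)
        ms.append(m)
        xs.append(x)
    return np.array(ms), np.array(xs)


def _free_ligand(x_total: float, m_total: float, sites: tuple[SiteClass, ...]) -> float:
    """Free titrant concentration from mass balance.

    One site class: closed-form quadratic.  Two: bracketed Brent solve of the
    monotone mass-balance residual to |f| < 1e-12 * x_total.
    """
    if x_total <= 0.0:
        return 0.0

    def residual(x_free: float) -> float:
        bound = sum(s.n * m_total * s.K * x_free / (1.0 + s.K * x_free) for s in sites)
        return x_free + bound - x_total

    def slope(x_free: float) -> float:
        return 1.0 + sum(
            s.n * m_total * s.K / (1.0 + s.K * x_free) ** 2 for s in sites
        )

    def polish(x_free: float) -> float:
        # Newton steps; the residual is monotone increasing so the iteration
        # is safely clamped to [0, x_total]
        for _ in range(4):
            x_free = min(max(x_free - residual(x_free) / slope(x_free), 0.0), x_total)
        return x_free

    if len(sites) == 1:
        s = sites[0]
        # K x^2 + b x - x_total = 0, cancellation-free branch on sign(b)
        b = 1.0 + s.K * (s.n * m_total - x_total)
        disc_sqrt = math.sqrt(b * b + 4.0 * s.K * x_total)
        if b >= 0.0:
            x_free = 2.0 * x_total / (b + disc_sqrt)
        else:
            x_free = (-b + disc_sqrt) / (2.0 * s.K)
        x_free = polish(min(max(x_free, 0.0), x_total))
    else:
        x_free = optimize.brentq(
            residual, 0.0, x_total, xtol=1e-14 * max(x_total, 1e-30), rtol=8.9e-16
        )
        x_free = polish(float(x_free))
    assert abs(residual(x_free)) <= 1e-10 * x_total
    return float(x_free)


def model_heats(params: BindingParams, protocol: TitrationProtocol) -> np.ndarray:
    """Per-injection heats (kcal per mole of injectant) of the binding model."""
    v0_l = protocol.cell_volume_ul * 1e-6
    m_tot, x_tot = _total_concentrations(protocol)
    q_prev = 0.0
    heats = np.empty(protocol.n_injections)
    for i, v_ul in enumerate(protocol.injection_volumes_ul):
        x_free = _free_ligand(float(x_tot[i]), float(m_tot[i]), params.sites)
        q = v0_l * m_tot[i] * sum(
            s.n * s.dH * s.K * x_free / (1.0 + s.K * x_free) for s in params.sites
        )
        dv = v_ul / protocol.cell_volume_ul
        dq = q - q_prev + dv * (q + q_prev) / 2.0
        moles_injected = v_ul * 1e-6 * protocol.syringe_concentration_uM * 1e-6
        heats[i] = dq / moles_injected
        q_prev = q
    return heats


def simulate_itc(
    params: BindingParams,
    protocol: TitrationProtocol,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Isotherm:
    """Model heats plus independent Gaussian noise (kcal/mol of injectant)."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    heats = model_heats(params, protocol)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        heats = heats + rng.normal(0.0, noise_sd, size=heats.shape)
    return Isotherm(protocol=protocol, heats=heats)


def subtract_dilution(sample: Isotherm, blank: Isotherm) -> Isotherm:
    """Blank (titrant-into-buffer) heat subtraction, elementwise."""
    if len(sample.heats) != len(blank.heats):
        raise ValueError("sample and blank have different injection counts")
    return Isotherm(protocol=sample.protocol, heats=sample.heats - blank.heats)


def derive_thermo(params: BindingParams, temperature_K: float) -> list[dict[str, float]]:
    """Per site class: dG = -RT ln K, dS = (dH - dG)/T (kcal/mol/K), Kd."""
    out = []
    for s in params.sites:
        dG = -R_KCAL * temperature_K * math.log(s.K)
        out.append(
            {"dG": dG, "TdS": s.dH - dG, "dS": (s.dH - dG) / temperature_K, "Kd": s.Kd}
        )
    return out


# ---------------------------------------------------------------------------
# fitting


def _unpack(theta: np.ndarray, n_classes: int) -> BindingParams:
    sites = []
    for j in range(n_classes):
        n, lnk, dh = theta[3 * j : 3 * j + 3]
        sites.append(SiteClass(n=float(n), K=float(math.exp(lnk)), dH=float(dh)))
    return BindingParams(sites=tuple(sites))


def fit_isotherm(
    isotherm: Isotherm,
    model: str = "one-site",
    n_starts: int = 20,
    seed: int = 0,
    drop_first: bool = False,
) -> BindingFit:
    """Least-squares fit of the one- or two-site model to an isotherm.

    Multi-start from seeded initial points dispersed over Kd in
    [1 nM, 100 μM], n in (0, 2] per class, and dH near the observed heat
    scale; the best converged optimum is returned with asymptotic standard
    errors from the Jacobian.  Two-site fits are reported weakest site
    first (K_1 < K_2).  ``drop_first`` excludes injection 1 from the
    residuals (common practice against syringe-tip pre-mixing artifacts)
    while keeping it in the dilution bookkeeping.
    """
    if model not in ("one-site", "two-site"):
        raise ValueError(f"unknown model {model!r}")
    n_classes = 1 if model == "one-site" else 2
    n_params = 3 * n_classes
    y = isotherm.heats
    first = 1 if drop_first else 0
    if len(y) - first < n_params + 3:
        raise ValueError("too few injections for the requested model")

    protocol = isotherm.protocol
    y = y[first:]

    def residuals(theta: np.ndarray) -> np.ndarray:
        try:
            p = _unpack(theta, n_classes)
        except ValueError:
            return np.full_like(y, 1e6)
        return model_heats(p, protocol)[first:] - y

    scale = float(np.max(np.abs(y))) or 1.0
    rng = np.random.default_rng(seed)
    lo = np.tile([1e-3, math.log(1e4), -40.0 * scale / 10.0], n_classes)
    hi = np.tile([4.0, math.log(1e9), 40.0 * scale / 10.0], n_classes)

    starts = []
    for _ in range(n_starts):
        theta0 = np.empty(n_params)
        for j in range(n_classes):
            theta0[3 * j] = rng.uniform(0.1, 1.5)
            theta0[3 * j + 1] = rng.uniform(math.log(1e5), math.log(1e8))
            theta0[3 * j + 2] = rng.choice([-1.0, 1.0]) * rng.uniform(0.2, 3.0) * scale
        starts.append(theta0)

    best = None
    n_ok = 0
    for theta0 in starts:
        try:
            res = optimize.least_squares(
                residuals, theta0, bounds=(lo, hi), method="trf",
                xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=4000,
            )
        except Exception:
            continue
        if not res.success and not np.isfinite(res.cost):
            continue
        n_ok += 1
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("ITC fit failed to converge from every start")

    theta = best.x
    # order site classes weakest first (K1 < K2)
    order = np.argsort([theta[3 * j + 1] for j in range(n_classes)])
    theta = np.concatenate([theta[3 * j : 3 * j + 3] for j in order])
    params = _unpack(theta, n_classes)

    rss = float(2.0 * best.cost)
    n_obs = len(y)
    # asymptotic covariance from the Jacobian at the optimum
    jac = best.jac[:, list(np.concatenate([np.arange(3 * j, 3 * j + 3) for j in order]))]
    dof = max(n_obs - n_params, 1)
    s2 = rss / dof
    stderr: dict[str, float | None] = {}
    names = []
    for j in range(n_classes):
        suffix = "" if n_classes == 1 else str(j + 1)
        names += [f"n{suffix}", f"lnK{suffix}", f"dH{suffix}"]
    try:
        cov = s2 * np.linalg.inv(jac.T @ jac)
        for k, name in enumerate(names):
            stderr[name] = float(math.sqrt(max(cov[k, k], 0.0)))
    except np.linalg.LinAlgError:
        stderr = {name: None for name in names}

    k_free = n_params + 1  # + residual variance
    aicc = n_obs * math.log(max(rss / n_obs, 1e-300)) + 2 * k_free
    if n_obs - k_free - 1 > 0:
        aicc += 2 * k_free * (k_free + 1) / (n_obs - k_free - 1)

    return BindingFit(
        params=params,
        stderr=stderr,
        rss=rss,
        aicc=aicc,
        converged=True,
        n_starts_converged=n_ok,
        temperature_K=protocol.temperature_K,
    )


# ---------------------------------------------------------------------------
# CSV dialect


CSV_HEADER = ["injection", "volume_ul", "heat_kcal_per_mol"]


def write_isotherm_csv(isotherm: Isotherm, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(CSV_HEADER)
        for i, (v, q) in enumerate(
            zip(isotherm.protocol.injection_volumes_ul, isotherm.heats), start=1
        ):
            w.writerow([i, f"{v:g}", f"{q:.10g}"])


def read_isotherm_csv(path: str | Path, protocol: TitrationProtocol | None = None) -> Isotherm:
    """Read the isotherm CSV dialect; protocol concentrations/volume/temperature
    may be supplied separately (the CSV carries injection volumes and heats)."""
    text = Path(path).read_text()
    rows = list(csv.reader(io.StringIO(text)))
    if not rows or [c.strip() for c in rows[0]] != CSV_HEADER:
        raise ValueError(f"bad isotherm CSV header in {path}: expected {CSV_HEADER}")
    volumes, heats = [], []
    for row in rows[1:]:
        if not row:
            continue
        volumes.append(float(row[1]))
        heats.append(float(row[2]))
    base = protocol or TitrationProtocol()
    proto = replace(base, injection_volumes_ul=tuple(volumes))
    return Isotherm(protocol=proto, heats=np.array(heats))
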