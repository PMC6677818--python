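"""Single-site ITC binding model and fitter; Michaelis-Menten for pNPP.

The isothermal titration calorimetry (ITC) forward model is the standard
single-site (Wiseman) treatment under the constant-volume perfusion
convention: each injection of volume v into a cell of volume V0 dilutes the
current cell contents by (1 - v/V0) and adds titrant v*[syringe]/V0.  At
each composition the bound-complex concentration follows from the exact
single-site quadratic, and the differential heat of injection i is

    q_i = dH * V0 * ([B]_i - [B]_{i-1} * (1 - v_i/V0))

with the dilution term accounting for complex displaced into the overflow.
Fitting (n, K_D, dH) to the per-injection heats by Levenberg-Marquardt
(K_D on a log scale) yields the thermodynamics reported for such
experiments: dG = R*T*ln(K_D) and T*dS = dH - dG, with
R = 1.987e-3 kcal mol^-1 K^-1.

The pNPP phosphatase assay is handled by Beer-Lambert conversion of A405
(epsilon = 18,000 M^-1 cm^-1, 0.3 cm path) and a Michaelis-Menten fit
v = Vmax*[S]/(Km + [S]) with kcat = Vmax/[E]_total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, TextIO, Union

import lmfit
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

R_KCAL = 1.987e-3  # kcal mol^-1 K^-1
DEFAULT_TEMPERATURE = 298.15  # K ("at 25 C")
KCAL_TO_UCAL = 1e9

PNPP_EPSILON = 18000.0  # M^-1 cm^-1 at 405 nm
PNPP_PATH_CM = 0.3  # 96-well plate optical path


@dataclass
class ItcExperiment:
    """Injection schedule and measured heats for one titration.

    Concentrations molar, volumes liters, heats ucal per injection.
    """

    cell_concentration: float  # macromolecule in the cell (e.g. CN)
    syringe_concentration: float  # titrant (e.g. NHE1ct)
    cell_volume: float
    injection_volumes: np.ndarray
    heats: Optional[np.ndarray] = None
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self):
        self.injection_volumes = np.asarray(self.injection_volumes, dtype=float)
        if self.heats is not None:
            self.heats = np.asarray(self.heats, dtype=float)
            if len(self.heats) != len(self.injection_volumes):
                raise ValueError("number of heats must equal number of injections")
        if self.cell_concentration <= 0 or self.syringe_concentration <= 0:
            raise ValueError("concentrations must be positive")
        if self.cell_volume <= 0 or np.any(self.injection_volumes <= 0):
            raise ValueError("volumes must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes)

    def compositions(self):
        """Total macromolecule and titrant in the cell after each injection."""
        M = np.empty(self.n_injections)
        X = np.empty(self.n_injections)
        m, x = self.cell_concentration, 0.0
        for i, v in enumerate(self.injection_volumes):
            d = 1.0 - v / self.cell_volume
            m *= d
            x = x * d + self.syringe_concentration * v / self.cell_volume
            M[i], X[i] = m, x
        return M, X


def default_schedule(
    cell_concentration: float = 5e-6,
    syringe_concentration: float = 50e-6,
    n_injections: int = 25,
    injection_volume: float = 10e-6,
    cell_volume: float = 1.4e-3,
    temperature: float = DEFAULT_TEMPERATURE,
) -> ItcExperiment:
    """25 x 10 uL injections of 50 uM titrant into 5 uM in a 1.4 mL cell."""
    return ItcExperiment(
        cell_concentration=cell_concentration,
        syringe_concentration=syringe_concentration,
        cell_volume=cell_volume,
        injection_volumes=np.full(n_injections, injection_volume),
        temperature=temperature,
    )


@dataclass
class BindingFit:
    n: float
    K_D: float  # molar
    dH: float  # kcal mol^-1
    dG: float  # kcal mol^-1
    TdS: float  # kcal mol^-1
    n_se: float = np.nan
    K_D_se: float = np.nan
    dH_se: float = np.nan
    c_value: float = np.nan
    converged: bool = True


@dataclass
class MmFit:
    Km: float  # molar
    Vmax: float  # molar s^-1
    kcat: float  # s^-1
    enzyme_total: float  # molar
    Km_se: float = np.nan
    Vmax_se: float = np.nan
    converged: bool = True


def _bound_complex(n: float, K_D: float, M_tot, X_tot):
    """Exact single-site quadratic for the bound-titrant concentration.

    ``n`` identical independent sites on the macromolecule: total site
    concentration n*M binds titrant X with dissociation constant K_D.
    """
    S = n * np.asarray(M_tot, dtype=float)
    X = np.asarray(X_tot, dtype=float)
    b = S + X + K_D
    disc = b * b - 4.0 * S * X
    return 0.5 * (b - np.sqrt(np.maximum(disc, 0.0)))


def wiseman_heats(
    n: float, K_D: float, dH: float, experiment: ItcExperiment
) -> np.ndarray:
    """Per-injection heats (ucal) of the single-site model on a schedule.

    ``dH`` in kcal mol^-1 of injectant-binding events; K_D molar.
    """
    if K_D <= 0:
        raise ValueError("K_D must be positive")
    if n <= 0:
        raise ValueError("stoichiometry n must be positive")
    M, X = experiment.compositions()
    B = _bound_complex(n, K_D, M, X)
    heats = np.empty(experiment.n_injections)
    prev = 0.0
    for i, v in enumerate(experiment.injection_volumes):
        d = 1.0 - v / experiment.cell_volume
        heats[i] = dH * KCAL_TO_UCAL * experiment.cell_volume * (B[i] - prev * d)
        prev = B[i]
    return heats


def fit_itc(experiment: ItcExperiment, exclude_first: bool = False) -> BindingFit:
    """Least-squares fit of (n, K_D, dH) to per-injection heats.

    K_D is fitted on a log scale for conditioning; standard errors come from
    the covariance at the optimum (K_D by error propagation).  The Wiseman
    c-value n*[cell]/K_D is reported, with a logged warning outside the
    informative range [1, 1000].  ``exclude_first`` drops the first
    injection (common practice when its volume is unreliable).
    """
    if experiment.heats is None:
        raise ValueError("experiment carries no measured heats")
    if experiment.n_injections < 10:
        raise ValueError("at least 10 injections are required for a stable fit")
    heats = experiment.heats
    sel = np.ones(len(heats), dtype=bool)
    if exclude_first:
        sel[0] = False

    # initialisation: assume near-saturation so the cumulative heat reflects
    # n*dH*V0*[M]; start K_D an order of magnitude below the cell concentration
    total = float(np.sum(heats))
    dh0 = total / (KCAL_TO_UCAL * experiment.cell_volume * experiment.cell_concentration)
    if dh0 == 0:
        dh0 = -1.0
    kd0 = experiment.cell_concentration / 10.0

    params = lmfit.Parameters()
    params.add("n", value=1.0, min=1e-3)
    params.add("lnKd", value=np.log(kd0))
    params.add("dH", value=dh0)

    def residual(p):
        model = wiseman_heats(
            p["n"].value, np.exp(p["lnKd"].value), p["dH"].value, experiment
        )
        return (heats - model)[sel]

    result = lmfit.minimize(residual, params, method="leastsq")
    converged = bool(result.success)
    if not converged:
        logger.warning("ITC fit did not converge: %s", result.message)
    n = float(result.params["n"].value)
    K_D = float(np.exp(result.params["lnKd"].value))
    dH = float(result.params["dH"].value)
    dG, TdS = derive_thermo(K_D, dH, experiment.temperature)
    ln_se = result.params["lnKd"].stderr
    c = n * experiment.cell_concentration / K_D
    if not 1.0 <= c <= 1000.0:
        logger.warning("c-value %.3g outside the informative range [1, 1000]", c)
    n_se = result.params["n"].stderr
    dH_se = result.params["dH"].stderr
    return BindingFit(
        n=n,
        K_D=K_D,
        dH=dH,
        dG=dG,
        TdS=TdS,
        n_se=float(n_se) if n_se is not None else np.nan,
        K_D_se=K_D * float(ln_se) if ln_se is not None else np.nan,
        dH_se=float(dH_se) if dH_se is not None else np.nan,
        c_value=c,
        converged=converged,
    )


def derive_thermo(K_D: float, dH: float, T: float = DEFAULT_TEMPERATURE):
    """(dG, TdS) in kcal mol^-1 from K_D (molar) and dH at temperature T."""
    if K_D <= 0 or T <= 0:
        raise ValueError("K_D and T must be positive")
    dG = R_KCAL * T * np.log(K_D)
    return dG, dH - dG


def absorbance_to_concentration(
    A405, epsilon: float = PNPP_EPSILON, path: float = PNPP_PATH_CM
):
    """Beer-Lambert conversion A/(epsilon*l); negative blanked A clips to 0."""
    A405 = np.asarray(A405, dtype=float)
    if np.any(A405 < 0):
        logger.warning("negative blank-subtracted absorbance clipped to 0")
        A405 = np.clip(A405, 0.0, None)
    conc = A405 / (epsilon * path)
    return float(conc) if conc.ndim == 0 else conc


def michaelis_menten(S, Vmax: float, Km: float):
    S = np.asarray(S, dtype=float)
    return Vmax * S / (Km + S)


def fit_michaelis_menten(
    substrate: Sequence[float], rates: Sequence[float], enzyme_total: float
) -> MmFit:
    """Fit v = Vmax*[S]/(Km+[S]); kcat = Vmax/[E]_total.

    Substrate molar, rates molar s^-1.  Warns when fewer than 5 points are
    supplied or the substrate range does not bracket the fitted Km.
    """
    S = np.asarray(substrate, dtype=float)
    v = np.asarray(rates, dtype=float)
    if len(S) != len(v):
        raise ValueError("substrate and rate arrays must align")
    if enzyme_total <= 0:
        raise ValueError("enzyme_total must be positive")
    if len(S) < 5:
        logger.warning("fewer than 5 substrate points; Km/Vmax poorly constrained")
    vmax0 = float(v.max()) if v.max() > 0 else 1e-12
    km0 = float(np.median(S[S > 0])) if np.any(S > 0) else 1e-6
    params = lmfit.Parameters()
    params.add("Vmax", value=vmax0, min=0.0)
    params.add("Km", value=km0, min=1e-15)
    result = lmfit.minimize(
        lambda p: v - michaelis_menten(S, p["Vmax"].value, p["Km"].value),
        params,
        method="leastsq",
    )
    converged = bool(result.success)
    Vmax = float(result.params["Vmax"].value)
    Km = float(result.params["Km"].value)
    if v.max() <= 0:
        logger.warning("all rates are zero; Vmax ~ 0")
        converged = False
    elif not (S.min() < Km < S.max()):
        logger.warning("substrate range does not bracket the fitted Km")
    vm_se = result.params["Vmax"].stderr
    km_se = result.params["Km"].stderr
    return MmFit(
        Km=Km,
        Vmax=Vmax,
        kcat=Vmax / enzyme_total,
        enzyme_total=enzyme_total,
        Km_se=float(km_se) if km_se is not None else np.nan,
        Vmax_se=float(vm_se) if vm_se is not None else np.nan,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def write_itc_csv(experiment: ItcExperiment, dest: Union[str, TextIO]) -> None:
    """Header block ('#key value') with the schedule, then per-injection rows."""
    if isinstance(dest, str):
        with open(dest, "w") as fh:
            write_itc_csv(experiment, fh)
        return
    dest.write(f"#cell_concentration_M {experiment.cell_concentration:.10g}\n")
    dest.write(f"#syringe_concentration_M {experiment.syringe_concentration:.10g}\n")
    dest.write(f"#cell_volume_L {experiment.cell_volume:.10g}\n")
    dest.write(f"#temperature_K {experiment.temperature:.10g}\n")
    dest.write("injection_index,injection_volume_uL,heat_ucal\n")
    heats = experiment.heats if experiment.heats is not None else np.full(
        experiment.n_injections, np.nan
    )
    for i, (v, q) in enumerate(zip(experiment.injection_volumes, heats), start=1):
        dest.write(f"{i},{v * 1e6:.10g},{q:.10g}\n")


def read_itc_csv(source: Union[str, TextIO]) -> ItcExperiment:
    if isinstance(source, str):
        with open(source) as fh:
            return read_itc_csv(fh)
    meta = {}
    lines = []
    for raw in source:
        if raw.startswith("#"):
            key, _, value = raw[1:].strip().partition(" ")
            meta[key] = float(value)
        else:
            lines.append(raw)
    required = {"cell_concentration_M", "syringe_concentration_M", "cell_volume_L"}
    missing = required - set(meta)
    if missing:
        raise ValueError(f"ITC CSV header missing: {sorted(missing)}")
    import io

    df = pd.read_csv(io.StringIO("".join(lines)))
    return ItcExperiment(
        cell_concentration=meta["cell_concentration_M"],
        syringe_concentration=meta["syringe_concentration_M"],
        cell_volume=meta["cell_volume_L"],
        injection_volumes=df["injection_volume_uL"].to_numpy() * 1e-6,
        heats=df["heat_ucal"].to_numpy(),
        temperature=meta.get("temperature_K", DEFAULT_TEMPERATURE),
    )


def write_pnpp_csv(substrate_M, rates, dest: Union[str, TextIO]) -> None:
    df = pd.DataFrame(
        {"substrate_uM": np.asarray(substrate_M) * 1e6, "rate_M_per_s": rates}
    )
    df.to_csv(dest, index=False, float_format="%.10g")


def read_pnpp_csv(source: Union[str, TextIO]):
    df = pd.read_csv(source, comment="#")
    if "substrate_uM" not in df.columns:
        raise ValueError("pNPP CSV must have a substrate_uM column")
    S = df["substrate_uM"].to_numpy() * 1e-6
    if "rate_M_per_s" in df.columns:
        v = df["rate_M_per_s"].to_numpy()
    elif "A405" in df.columns:
        raise ValueError(
            "raw A405 supplied; convert with absorbance_to_concentration and a "
            "reaction time first"
        )
    else:
        raise ValueError("pNPP CSV must have rate_M_per_s (or A405)")
    return S, v
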