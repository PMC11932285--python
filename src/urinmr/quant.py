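"""Internal-standard quantification of processed 1D 1H spectra.

The chain mirrors standard quantitative urinary NMR practice: each
overlap-free resonance is integrated, the integral divided by the number
of protons generating it, and the per-proton integral compared with the
per-proton integral of the TSP reference singlet of known concentration:

    conc_m [mM] = (I_m / n_m) / (I_TSP / 9) * tsp_conc_mM

Molar concentrations are then divided by the creatinine concentration —
itself quantified from the 4.05 ppm singlet through the same formula — to
give dilution-corrected values in µmol/mmol creatinine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ConcentrationMatrix, MetaboliteSignal, Spectrum
from .synthdata import CREATININE_NAME, TSP_NAME, WINDOW_HALF_WIDTH_PPM

logger = logging.getLogger(__name__)


@dataclass
class QuantConfig:
    """Quantification constants.

    ``tsp_conc_mM`` defaults to 1.82 mM, the spiked internal-standard
    concentration in urine. Window widths are config-exposed because
    neither the TSP integration width nor satellite handling is a
    universal convention.
    """

    tsp_conc_mM: float = 1.82
    tsp_protons: int = 9
    tsp_window_ppm: tuple[float, float] = (-WINDOW_HALF_WIDTH_PPM,
                                           WINDOW_HALF_WIDTH_PPM)
    creatinine_window_ppm: tuple[float, float] = (4.05 - WINDOW_HALF_WIDTH_PPM,
                                                  4.05 + WINDOW_HALF_WIDTH_PPM)
    creatinine_protons: int = 3

    def __post_init__(self) -> None:
        if self.tsp_conc_mM <= 0:
            raise ValueError("tsp_conc_mM must be > 0")


def integrate_window(spectrum: Spectrum, window: tuple[float, float]) -> float:
    """Trapezoidal integral of intensity over a half-open ppm window.

    The intensity is linearly interpolated at the window bounds so the
    integral covers exactly [lo, hi) regardless of grid alignment.
    Requires at least two grid points inside the window.
    """
    lo, hi = window
    ppm, y = spectrum.ppm, spectrum.intensity
    if lo < ppm[0] or hi > ppm[-1]:
        raise ValueError(f"window [{lo}, {hi}) outside ppm range "
                         f"[{ppm[0]}, {ppm[-1]}]")
    inside = (ppm >= lo) & (ppm < hi)
    if inside.sum() < 2:
        raise ValueError(f"fewer than 2 grid points inside window [{lo}, {hi})")
    xs = np.concatenate(([lo], ppm[inside], [hi]))
    ys = np.concatenate(([np.interp(lo, ppm, y)], y[inside],
                         [np.interp(hi, ppm, y)]))
    # drop duplicated abscissae if a grid point sits exactly on a bound
    keep = np.concatenate(([True], np.diff(xs) > 0))
    return float(np.trapezoid(ys[keep], xs[keep]))


def _clamped_integral(spectrum: Spectrum, window: tuple[float, float],
                      name: str) -> float:
    integral = integrate_window(spectrum, window)
    if integral < 0:
        logger.warning("negative integral (%.3g) for %s in %s; clamped to 0",
                       integral, name, spectrum.subject_id or "<spectrum>")
        return 0.0
    return integral


def quantify(
    spectrum: Spectrum,
    library: list[MetaboliteSignal],
    quant_config: QuantConfig | None = None,
) -> pd.Series:
    """Molar concentrations (mM) for every library signal.

    The TSP and creatinine windows come from the quant config (they are
    reference constants, not library lookups); every other signal uses its
    library window. Negative integrals from noisy baselines are clamped to
    zero with a logged warning.
    """
    cfg = quant_config or QuantConfig()
    i_tsp = integrate_window(spectrum, cfg.tsp_window_ppm)
    if i_tsp <= 0:
        raise ValueError(
            f"non-positive TSP integral ({i_tsp:.3g}) in "
            f"{spectrum.subject_id or '<spectrum>'}: reference missing or invalid")
    tsp_per_proton = i_tsp / cfg.tsp_protons

    out: dict[str, float] = {}
    for sig in library:
        if sig.name == TSP_NAME:
            window, protons = cfg.tsp_window_ppm, cfg.tsp_protons
        elif sig.name == CREATININE_NAME:
            window, protons = cfg.creatinine_window_ppm, cfg.creatinine_protons
        else:
            window, protons = sig.window_ppm, sig.n_protons
        integral = _clamped_integral(spectrum, window, sig.name)
        out[sig.name] = (integral / protons) / tsp_per_proton * cfg.tsp_conc_mM
    return pd.Series(out, name=spectrum.subject_id)


def normalize_to_creatinine(molar_concs: pd.Series | dict[str, float],
                            creatinine_conc_mM: float) -> pd.Series:
    """mM -> µmol/mmol creatinine: 1000 * conc / creatinine (µmol/L over mmol/L)."""
    if creatinine_conc_mM <= 0:
        raise ValueError(f"creatinine concentration must be > 0, "
                         f"got {creatinine_conc_mM}")
    return pd.Series(molar_concs, dtype=float) * 1000.0 / creatinine_conc_mM


def build_matrix(
    spectra: list[Spectrum],
    labels: list[str] | pd.Series,
    library: list[MetaboliteSignal],
    quant_config: QuantConfig | None = None,
) -> ConcentrationMatrix:
    """Quantify a cohort of spectra into a creatinine-normalised table.

    One row per subject in input order; the TSP and creatinine reference
    entries are consumed by the normalisation and do not appear as columns.
    """
    if not spectra:
        raise ValueError("no spectra supplied")
    labels = list(labels)
    if len(labels) != len(spectra):
        raise ValueError("one group label required per spectrum")

    rows, ids = [], []
    for spec in spectra:
        try:
            molar = quantify(spec, library, quant_config)
            cre = molar[CREATININE_NAME]
            normalized = normalize_to_creatinine(molar, cre)
        except ValueError as err:
            raise ValueError(f"subject {spec.subject_id!r}: {err}") from err
        rows.append(normalized.drop([TSP_NAME, CREATININE_NAME]))
        ids.append(spec.subject_id)

    df = pd.DataFrame(rows, index=ids)
    return ConcentrationMatrix(values=df, groups=pd.Series(labels, index=ids))
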