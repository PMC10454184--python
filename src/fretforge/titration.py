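"""In vitro readout models: ratiometric FRET, redox titration, time courses.

The ratiometric efficiency is the acceptor-channel to donor-channel
emission intensity ratio I(530 nm)/I(475 nm) at 433 nm excitation.  The
glutathione titration treats the probe's a' active-site dithiol/disulfide
couple as a two-state equilibrium with the GSH/GSSG pair,

    ox + 2 GSH  <->  red + GSSG,
    K_eq = [red][GSSG] / ([ox][GSH]^2),

so with x = [GSH]^2/[GSSG] (molar) the oxidized fraction is
f_ox(x) = K_eq / (K_eq + x) and the observed ratio interpolates between
the endpoint ratios:

    R(x) = R_red + (R_ox - R_red) f_ox(x).

The fit estimates (K_eq, R_ox, R_red) by nonlinear least squares on
decade-spanning titrations, optionally with a nonparametric bootstrap.
Time courses are baseline-normalized by the pre-stimulation mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "EmissionSpectrum",
    "TitrationPoint",
    "RedoxFit",
    "FitError",
    "ratiometric_efficiency",
    "fraction_oxidized",
    "predict_ratio",
    "fit_titration",
    "normalize_timecourse",
    "read_spectrum_csv",
    "read_titration_csv",
    "read_timecourse_csv",
]

DONOR_NM = 475.0     # CFP emission read-out wavelength
FRET_NM = 530.0      # FRET (acceptor) emission read-out wavelength
EXCITATION_NM = 433.0


class FitError(RuntimeError):
    """Raised when the titration fit fails to converge; carries best-so-far."""

    def __init__(self, message: str, best: Optional["RedoxFit"] = None):
        super().__init__(message)
        self.best = best


@dataclass
class EmissionSpectrum:
    """Emission spectrum on an ascending wavelength grid (nm), 400-600 nm."""

    wavelengths: np.ndarray
    intensities: np.ndarray
    excitation: float = EXCITATION_NM

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.wavelengths.shape != self.intensities.shape:
            raise ValueError("wavelengths and intensities differ in length")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")


@dataclass(frozen=True)
class TitrationPoint:
    """One redox-buffer condition: [GSH], [GSSG] in molar, observed ratio."""

    gsh: float
    gssg: float
    observed_ratio: float

    def __post_init__(self) -> None:
        if self.gsh <= 0 or self.gssg <= 0:
            raise ValueError("glutathione concentrations must be positive")

    @property
    def x(self) -> float:
        """[GSH]^2/[GSSG] in molar, the titration axis."""
        return self.gsh ** 2 / self.gssg


@dataclass
class RedoxFit:
    """Two-state titration fit: midpoint K_eq (M) and endpoint ratios."""

    k_eq: float
    r_ox: float
    r_red: float
    residual_norm: float = float("nan")
    k_eq_identifiable: bool = True
    ci: Optional[dict] = None           # bootstrap percentile intervals

    def __post_init__(self) -> None:
        if self.k_eq <= 0:
            raise ValueError("K_eq must be positive")


def ratiometric_efficiency(spectrum: EmissionSpectrum,
                           fret_nm: float = FRET_NM,
                           donor_nm: float = DONOR_NM) -> float:
    """I(530)/I(475), each intensity linearly interpolated on the grid."""
    w = spectrum.wavelengths
    for nm in (fret_nm, donor_nm):
        if nm < w[0] or nm > w[-1]:
            raise ValueError(f"{nm} nm outside the recorded range "
                             f"[{w[0]}, {w[-1]}]")
    i_fret = float(np.interp(fret_nm, w, spectrum.intensities))
    i_donor = float(np.interp(donor_nm, w, spectrum.intensities))
    if i_donor <= 0:
        raise ValueError("donor intensity at 475 nm is not positive; "
                         "ratio undefined")
    return i_fret / i_donor


def fraction_oxidized(x, k_eq: float):
    """Oxidized fraction f_ox = K_eq / (K_eq + x); x = [GSH]^2/[GSSG] in M.

    f_ox(0) = 1, f_ox(K_eq) = 0.5, strictly decreasing in x.  Accepts
    scalars or arrays.
    """
    x = np.asarray(x, dtype=np.float64)
    if np.any(x < 0):
        raise ValueError("x must be non-negative")
    if k_eq <= 0:
        raise ValueError("K_eq must be positive")
    out = k_eq / (k_eq + x)
    return float(out) if out.ndim == 0 else out


def predict_ratio(x, fit: RedoxFit):
    """R(x) = R_red + (R_ox - R_red) f_ox(x); R_ox at x=0, R_red as x -> inf."""
    f = fraction_oxidized(x, fit.k_eq)
    return fit.r_red + (fit.r_ox - fit.r_red) * f


def _as_dataframe(points) -> pd.DataFrame:
    if isinstance(points, pd.DataFrame):
        df = points.rename(columns={"gsh_M": "gsh", "gssg_M": "gssg",
                                    "ratio": "observed_ratio"})
        return df[["gsh", "gssg", "observed_ratio"]].astype(float)
    return pd.DataFrame(
        [(p.gsh, p.gssg, p.observed_ratio) for p in points],
        columns=["gsh", "gssg", "observed_ratio"])


def fit_titration(points: Union[Sequence[TitrationPoint], pd.DataFrame],
                  n_bootstrap: int = 0, seed: Optional[int] = None,
                  min_decades: float = 2.0) -> RedoxFit:
    """Fit (K_eq, R_ox, R_red) to a titration by nonlinear least squares.

    Requires at least four points whose x = [GSH]^2/[GSSG] values span at
    least ``min_decades`` decades.  The midpoint is parameterized as
    log10(K_eq), initialized by interpolating the x at which the observed
    ratio crosses the midpoint between its extremes; endpoints start at
    the extreme observed ratios.  When the observed dynamic range is
    negligible (a redox-insensitive construct) the midpoint is
    unidentifiable and the fit is flagged accordingly.

    With ``n_bootstrap > 0`` (1000 is the customary default), points are
    resampled with replacement, refit, and 95% percentile intervals
    attached; the procedure is deterministic for a given ``seed``.
    """
    df = _as_dataframe(points)
    if len(df) < 4:
        raise ValueError("need at least 4 titration points")
    x = (df["gsh"] ** 2 / df["gssg"]).to_numpy()
    ratios = df["observed_ratio"].to_numpy()
    if np.any(x <= 0):
        raise ValueError("x values must be positive")
    span = np.log10(x.max() / x.min())
    if span < min_decades:
        raise ValueError(
            f"x range spans {span:.2f} decades; need >= {min_decades}")

    fit = _fit_once(x, ratios)

    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        samples = []
        for _ in range(n_bootstrap):
            idx = rng.integers(0, len(x), size=len(x))
            try:
                b = _fit_once(x[idx], ratios[idx])
            except (FitError, ValueError):
                continue
            samples.append((np.log10(b.k_eq), b.r_ox, b.r_red))
        if samples:
            arr = np.asarray(samples)
            lo, hi = np.percentile(arr, [2.5, 97.5], axis=0)
            fit.ci = {
                "log10_k_eq": (float(lo[0]), float(hi[0])),
                "r_ox": (float(lo[1]), float(hi[1])),
                "r_red": (float(lo[2]), float(hi[2])),
                "n_resamples": len(samples),
            }
    return fit


def _fit_once(x: np.ndarray, ratios: np.ndarray) -> RedoxFit:
    r_hi, r_lo = float(ratios.max()), float(ratios.min())
    spread = r_hi - r_lo
    scale = max(abs(ratios).max(), 1e-12)

    # initialize the midpoint by interpolating where the ratio crosses the
    # half-way level, on the log10(x) axis
    order = np.argsort(x)
    lx, ly = np.log10(x[order]), ratios[order]
    if spread > 1e-12 * scale:
        mid_level = 0.5 * (r_hi + r_lo)
        sign = np.sign(ly - mid_level)
        crossings = np.flatnonzero(np.diff(sign) != 0)
        if crossings.size:
            i = crossings[0]
            frac = (mid_level - ly[i]) / (ly[i + 1] - ly[i])
            log_k0 = lx[i] + frac * (lx[i + 1] - lx[i])
        else:
            log_k0 = float(np.median(lx))
    else:
        log_k0 = float(np.median(lx))

    def residuals(theta):
        log_k, r_ox, r_red = theta
        f = 1.0 / (1.0 + x / 10.0 ** log_k)
        return r_red + (r_ox - r_red) * f - ratios

    theta0 = np.array([log_k0, r_hi, r_lo])
    result = least_squares(residuals, theta0, method="lm",
                           xtol=1e-14, ftol=1e-14, gtol=1e-14,
                           max_nfev=5000)
    log_k, r_ox, r_red = result.x
    fit = RedoxFit(
        k_eq=float(10.0 ** np.clip(log_k, -300, 300)),
        r_ox=float(r_ox), r_red=float(r_red),
        residual_norm=float(np.linalg.norm(result.fun)),
    )
    # the midpoint is unidentifiable when the two-state model explains
    # little beyond a constant response (a redox-insensitive construct);
    # report the flat fit in that case instead of overfitted endpoints
    sse_fit = float(result.fun @ result.fun)
    sse_const = float(((ratios - ratios.mean()) ** 2).sum())
    if sse_const <= (1e-12 * scale) ** 2 * len(x) or sse_fit > 0.2 * sse_const:
        mean_ratio = float(ratios.mean())
        fit = RedoxFit(
            k_eq=float(10.0 ** np.median(lx)),
            r_ox=mean_ratio, r_red=mean_ratio,
            residual_norm=float(np.sqrt(sse_const)),
            k_eq_identifiable=False,
        )
        return fit
    if not result.success:
        raise FitError(f"titration fit did not converge: {result.message}",
                       best=fit)
    return fit


def normalize_timecourse(values: np.ndarray, times: Optional[np.ndarray] = None,
                         baseline_end: Optional[float] = None,
                         baseline_mask: Optional[np.ndarray] = None
                         ) -> np.ndarray:
    """Divide a FRET/CFP ratio series by its pre-stimulation baseline mean.

    The baseline window is given either as ``baseline_end`` (samples with
    time < baseline_end; times default to the sample index) or as an
    explicit boolean ``baseline_mask``.  The normalized series has
    baseline mean exactly 1, so the operation is idempotent.
    """
    values = np.asarray(values, dtype=np.float64)
    if baseline_mask is not None:
        mask = np.asarray(baseline_mask, dtype=bool)
        if mask.shape != values.shape:
            raise ValueError("baseline_mask shape mismatch")
    else:
        if baseline_end is None:
            raise ValueError("give baseline_end or baseline_mask")
        t = np.arange(len(values)) if times is None \
            else np.asarray(times, dtype=np.float64)
        mask = t < baseline_end
    if not mask.any():
        raise ValueError("baseline window contains no samples")
    baseline = values[mask].mean()
    if baseline <= 0:
        raise ValueError("baseline mean is not positive")
    return values / baseline


# ---------------------------------------------------------------------------
# CSV I/O

def read_spectrum_csv(path: str | Path,
                      excitation: float = EXCITATION_NM) -> EmissionSpectrum:
    """Two-column CSV with header: wavelength_nm, intensity."""
    df = pd.read_csv(path)
    return EmissionSpectrum(df.iloc[:, 0].to_numpy(),
                            df.iloc[:, 1].to_numpy(), excitation=excitation)


def read_titration_csv(path: str | Path) -> list[TitrationPoint]:
    """CSV with header gsh_M, gssg_M, ratio."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    gsh = cols.get("gsh_m", df.columns[0])
    gssg = cols.get("gssg_m", df.columns[1])
    ratio = cols.get("ratio", df.columns[2])
    return [TitrationPoint(float(r[gsh]), float(r[gssg]), float(r[ratio]))
            for _, r in df.iterrows()]


def read_timecourse_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """CSV with header time_s, ratio; returns (times, ratios)."""
    df = pd.read_csv(path)
    return df.iloc[:, 0].to_numpy(np.float64), df.iloc[:, 1].to_numpy(np.float64)
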