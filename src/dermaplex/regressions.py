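"""Response-surface regressions for the plexus-mean concentration C_plex.

Ships the four published fitted relationships between C_plex and one swept
physiological variable, evaluates them exactly, locates their extrema, and
refits the same functional forms to new sweep data:

* plexus size (quadratic in ``p_size``, metres):
  ``C_plex = 2e7 p² − 1990.4 p + 0.0454``  (R² 0.94; minimum at the standard
  ~50 μm plexus size)
* plexus depth (quadratic in ``h_plex``, metres):
  ``C_plex = −199723 h² + 182.39 h − 0.0387``  (R² 0.95; maximum near 450 μm)
* blood velocity (exponential in ``v_b``, m/s):
  ``C_plex = 0.008 exp(−2038 v_b)``  (R² 0.97)
* pore density (linear in the fraction ``p_d``): ``C_plex = 0.0056 p_d + 0.002``

Input units are metres / m·s⁻¹ / fraction; with these units the quadratic
vertices land on the published standard values, which is how the units were
inferred. The depth quadratic's negative intercept is kept verbatim: these are
reference response curves, not concentration predictions, and are not clipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "RegressionFit",
    "Extremum",
    "PRINTED_FITS",
    "printed_fit",
    "eval_printed",
    "quadratic_extremum",
    "fit_surface",
]

FORMS = ("quadratic", "exponential", "linear")
_N_COEF = {"quadratic": 3, "exponential": 2, "linear": 2}


@dataclass(frozen=True)
class RegressionFit:
    """A fitted (or published) response curve.

    Coefficient conventions: quadratic ``(a, b, c) → a x² + b x + c``;
    exponential ``(a, b) → a exp(b x)``; linear ``(a, b) → a x + b``.
    """

    form: str
    coefficients: tuple[float, ...]
    r2: float | None = None
    input_variable: str | None = None

    def __post_init__(self):
        if self.form not in FORMS:
            raise ValueError(f"unknown form {self.form!r}")
        if len(self.coefficients) != _N_COEF[self.form]:
            raise ValueError(
                f"{self.form} form takes {_N_COEF[self.form]} coefficients, "
                f"got {len(self.coefficients)}"
            )
        if self.r2 is not None and not 0.0 <= self.r2 <= 1.0:
            raise ValueError(f"R² must lie in [0, 1], got {self.r2}")

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        a = self.coefficients
        if self.form == "quadratic":
            return a[0] * x**2 + a[1] * x + a[2]
        if self.form == "exponential":
            return a[0] * np.exp(a[1] * x)
        return a[0] * x + a[1]


# the published response surfaces, input units as inferred above
PRINTED_FITS: dict[str, RegressionFit] = {
    "size": RegressionFit("quadratic", (2e7, -1990.4, 0.0454), 0.94, "p_size"),
    "depth": RegressionFit("quadratic", (-199723.0, 182.39, -0.0387), 0.95, "h_plex"),
    "velocity": RegressionFit("exponential", (0.008, -2038.0), 0.97, "v_b"),
    "density": RegressionFit("linear", (0.0056, 0.002), None, "p_d"),
}


def printed_fit(name: str) -> RegressionFit:
    if name not in PRINTED_FITS:
        raise KeyError(f"unknown regression {name!r}; expected one of {tuple(PRINTED_FITS)}")
    return PRINTED_FITS[name]


def eval_printed(name: str, x: float):
    """Evaluate a published response curve at an SI input value."""
    val = printed_fit(name)(x)
    return float(val) if np.isscalar(x) or np.ndim(x) == 0 else val


@dataclass(frozen=True)
class Extremum:
    x: float
    value: float
    kind: str  # "minimum" | "maximum"


def quadratic_extremum(fit: RegressionFit) -> Extremum:
    """Vertex −b/(2a) of a quadratic fit, classified by the sign of a."""
    if fit.form != "quadratic":
        raise ValueError(f"extremum requires a quadratic fit, got {fit.form!r}")
    a, b, _ = fit.coefficients
    if a == 0:
        raise ValueError("degenerate quadratic (a = 0) has no extremum")
    x = -b / (2.0 * a)
    return Extremum(x=x, value=float(fit(x)), kind="minimum" if a > 0 else "maximum")


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0.0:
        return 0.0  # convention for constant data
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot


def fit_surface(
    xs: Sequence[float], ys: Sequence[float], form: str, input_variable: str | None = None
) -> RegressionFit:
    """Least-squares fit of one of the three response forms.

    The exponential is fitted by nonlinear least squares initialized from the
    log-linear fit (requires positive responses). Constant data returns the
    constant with R² = 0 by convention.
    """
    if form not in FORMS:
        raise ValueError(f"unknown form {form!r}")
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("xs and ys must be equal-length 1-D sequences")
    n_coef = _N_COEF[form]
    if len(np.unique(x)) < n_coef:
        raise ValueError(
            f"{form} fit needs at least {n_coef} distinct x values, got {len(np.unique(x))}"
        )
    if np.ptp(y) == 0.0:
        c = float(y[0])
        coef = {"quadratic": (0.0, 0.0, c), "linear": (0.0, c), "exponential": (c, 0.0)}[form]
        return RegressionFit(form, coef, 0.0, input_variable)

    if form in ("quadratic", "linear"):
        deg = 2 if form == "quadratic" else 1
        coef = np.polyfit(x, y, deg)
        fit = RegressionFit(form, tuple(float(c) for c in coef), None, input_variable)
    else:
        if np.any(y <= 0):
            raise ValueError("exponential fit requires positive responses")
        slope, intercept = np.polyfit(x, np.log(y), 1)
        p0 = (float(np.exp(intercept)), float(slope))
        popt, _ = curve_fit(lambda t, a, b: a * np.exp(b * t), x, y, p0=p0, maxfev=10000)
        fit = RegressionFit(form, (float(popt[0]), float(popt[1])), None, input_variable)
    return RegressionFit(fit.form, fit.coefficients, max(0.0, min(1.0, _r2(y, fit(x)))), input_variable)
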