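"""AFM nanoindentation: force curves to Young's moduli.

Polyacrylamide-gel stiffness is measured by indenting the gel with a
four-sided pyramidal cantilever tip and fitting the approach segment of the
force-displacement curve with the pyramidal contact model

    F = c * tan(theta) * E / (1 - nu^2) * delta^2

where ``theta`` is the tip's effective half-angle, ``nu`` the Poisson ratio
of the gel, ``delta`` the indentation depth, and ``c`` the geometry
coefficient of the regular four-sided pyramid (0.7453).  The indentation is
computed from the piezo displacement ``z`` and cantilever deflection ``d``
as ``delta = (z - z0) - d`` with ``z0`` the contact point; force is
``k * d`` with ``k`` the cantilever spring constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ForceCurve",
    "IndenterModel",
    "ModulusFit",
    "pyramid_force",
    "find_contact_point",
    "fit_young_modulus",
    "grid_summary",
]

#: Geometry coefficient of a regular four-sided pyramidal indenter.
PYRAMID_COEFFICIENT = 0.7453


@dataclass
class IndenterModel:
    """Pyramidal tip geometry and sample elasticity assumptions.

    half_angle: effective face half-angle in degrees (18 for MLCT-D tips);
    poisson_ratio: 0.5 for incompressible polyacrylamide;
    geometry_coefficient: prefactor c of the contact model.
    """

    half_angle: float = 18.0
    poisson_ratio: float = 0.5
    geometry_coefficient: float = PYRAMID_COEFFICIENT

    def __post_init__(self):
        if not 0 < self.half_angle < 90:
            raise ValueError("half_angle must be in (0, 90) degrees")
        if not 0 <= self.poisson_ratio <= 0.5:
            raise ValueError("poisson_ratio must be in [0, 0.5]")

    @property
    def prefactor(self) -> float:
        """c * tan(theta) / (1 - nu^2); multiply by E [Pa] and delta^2 [m^2] for N."""
        return (self.geometry_coefficient * np.tan(np.radians(self.half_angle))
                / (1.0 - self.poisson_ratio ** 2))


@dataclass
class ForceCurve:
    """Approach segment of an AFM force-displacement curve.

    z_um is the piezo (cantilever-base) displacement toward the sample and
    deflection_um the cantilever deflection, both in um; spring_constant in
    N/m converts deflection to force.
    """

    z_um: np.ndarray
    deflection_um: np.ndarray
    spring_constant: float = 0.03
    ramp_size: float = 5.0
    ramp_speed: float = 10.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.z_um = np.asarray(self.z_um, dtype=float)
        self.deflection_um = np.asarray(self.deflection_um, dtype=float)
        if self.z_um.shape != self.deflection_um.shape:
            raise ValueError("z and deflection must have equal length")
        if self.spring_constant <= 0:
            raise ValueError("spring constant must be positive")

    @property
    def force_n(self) -> np.ndarray:
        """Force in newtons: k [N/m] * deflection [m]."""
        return self.spring_constant * self.deflection_um * 1e-6


@dataclass
class ModulusFit:
    """Result of fitting the pyramidal contact model to one curve."""

    E: float                      # Pa
    contact_index: int
    contact_z: float              # um
    fit_range: tuple              # (delta_min, delta_max) um
    residual_rms: float           # N
    n_fit: int

    def __post_init__(self):
        if self.E <= 0:
            raise ValueError("fitted Young's modulus must be positive")


def pyramid_force(indentation_um, model: IndenterModel, E: float) -> np.ndarray:
    """Force (N) exerted by a four-sided pyramidal tip at a given indentation.

    Quadratic in indentation and linear in E.
    """
    delta = np.asarray(indentation_um, dtype=float)
    if np.any(delta < 0):
        raise ValueError("indentation must be non-negative")
    return model.prefactor * E * (delta * 1e-6) ** 2


def find_contact_point(curve: ForceCurve, baseline_fraction: float = 0.3,
                       n_sigma: float = 3.0, refine_window: int = 15) -> tuple:
    """Locate the tip-sample contact point on the approach segment.

    A linear baseline is fitted to the initial pre-contact samples; the
    coarse contact point is the last sample before a sustained rise of the
    deflection above baseline + n_sigma * sigma.  The estimate is then
    refined by a piecewise fit: for candidate indices around the coarse
    point, the curve is modeled as baseline before and baseline + quadratic
    after, and the candidate minimizing the total squared residual wins.

    Returns ``(index, z0)``.
    """
    z, d = curve.z_um, curve.deflection_um
    n = len(z)
    n_base = max(min(int(baseline_fraction * n), n // 10), 20)
    if n < n_base + 5:
        raise ValueError("curve too short: need a pre-contact baseline of >= 20 samples")

    def _coarse_from(nb):
        base_coef = np.polyfit(z[:nb], d[:nb], 1)
        resid = d - np.polyval(base_coef, z)
        sigma = max(float(np.std(resid[:nb])), 1e-12)
        above = resid > n_sigma * sigma
        # sustained rise: first index from which the deflection stays above
        # threshold for at least 5 consecutive samples (or to the end)
        first = None
        for i in np.flatnonzero(above):
            stop = min(i + 5, n)
            if above[i:stop].all():
                first = int(i)
                break
        if first is None:
            raise ValueError("no contact point found: curve never leaves the baseline")
        return max(first - 1, 0), resid

    coarse, resid = _coarse_from(n_base)

    # piecewise refinement: the coarse crossing always lags the true contact
    # (the onset force is below the noise threshold), so candidates are
    # searched mostly backwards.  For each candidate z0 the post segment is
    # predicted with the exact implicit contact model k d = C ((z-z0) - d)^2,
    # with C estimated as a median over the deepest half of the indentation
    # (high signal-to-noise, negligible errors-in-variables bias), and the
    # full-curve squared residual decides.
    k = curve.spring_constant

    def _sse(i):
        # baseline refitted per candidate so its extrapolation error does
        # not tilt the post-contact residuals
        bc = np.polyfit(z[: max(i - 2, 2)], d[: max(i - 2, 2)], 1)
        resid = d - np.polyval(bc, z)
        u = (z[i + 1:] - z[i]) * 1e-6          # m
        dm = resid[i + 1:] * 1e-6              # m
        delta = u - dm
        good = delta > 0
        if good.sum() < 5:
            return None
        uu, dd, de = u[1:][good[1:]], dm[1:][good[1:]], delta[1:][good[1:]]
        top = uu >= np.median(uu)
        C = float(np.median(k * dd[top] / de[top] ** 2))
        if C <= 0:
            return None
        disc = (2 * C * u + k) ** 2 - 4 * C ** 2 * u ** 2
        d_pred = np.where(u > 0, (2 * C * u + k - np.sqrt(np.clip(disc, 0, None)))
                          / (2 * C), 0.0)
        return (float(np.sum(resid[: i + 1] ** 2)) * 1e-12
                + float(np.sum((dm - d_pred) ** 2)))

    lo = max(n_base // 2, coarse - max(10 * refine_window, n // 4))
    hi = min(n - 6, coarse + refine_window)
    best_i, best_sse = coarse, np.inf
    for i in range(lo, hi + 1, 2):
        s = _sse(i)
        if s is not None and s < best_sse * (1.0 - 1e-12):
            best_sse, best_i = s, i
    for i in range(max(lo, best_i - 2), min(hi, best_i + 2) + 1):
        s = _sse(i)
        if s is not None and s < best_sse * (1.0 - 1e-12):
            best_sse, best_i = s, i
    return best_i, float(z[best_i])


def fit_young_modulus(curve: ForceCurve, model: IndenterModel | None = None,
                      fit_fraction: float = 1.0, max_indentation_um: float = 1.0,
                      contact: tuple | None = None) -> ModulusFit:
    """Fit the pyramidal contact model to a force curve and return E.

    The indentation is ``delta = (z - z0) - (d - baseline)`` and the force
    ``k * (d - baseline)``; a linear least-squares fit of force against
    delta^2 over indentations up to ``fit_fraction`` of the maximum (capped
    at ``max_indentation_um``, respecting the finite tip height) yields E
    through the model prefactor.
    """
    if model is None:
        model = IndenterModel()
    if contact is None:
        contact = find_contact_point(curve)
    ci0, _ = contact

    z, d = curve.z_um, curve.deflection_um
    n = len(z)

    def _fit_at(ci):
        z0 = z[ci]
        n_base = max(ci - 2, 2)
        base_coef = np.polyfit(z[:n_base], d[:n_base], 1)
        d_corr = d - np.polyval(base_coef, z)
        post = slice(ci + 1, None)
        delta = (z[post] - z0) - d_corr[post]
        force = curve.spring_constant * d_corr[post] * 1e-6
        good = delta > 0
        delta, force = delta[good], force[good]
        if delta.size < 3:
            return None
        dmax = min(fit_fraction * float(delta.max()), max_indentation_um)
        sel = delta <= dmax
        if sel.sum() < 3:
            sel = np.zeros(delta.size, dtype=bool)
            sel[np.argsort(delta)[:3]] = True
        x = (delta[sel] * 1e-6) ** 2
        y = force[sel]
        # free intercept absorbs residual baseline-extrapolation error that
        # would otherwise bias A on noisy soft-gel curves
        M = np.column_stack([x, np.ones_like(x)])
        (A, _b), *_ = np.linalg.lstsq(M, y, rcond=None)
        # errors-in-variables refinement: measured deflection noise enters
        # the indentation regressor (delta = u - d), attenuating A for stiff
        # samples; rebuild delta from the model-predicted deflection instead
        u_sel = (z[post][good][sel] - z0) * 1e-6
        k = curve.spring_constant
        for _ in range(3):
            if A <= 0:
                break
            disc = (2 * A * u_sel + k) ** 2 - 4 * A ** 2 * u_sel ** 2
            d_pred = (2 * A * u_sel + k - np.sqrt(np.clip(disc, 0, None))) / (2 * A)
            x = (u_sel - d_pred) ** 2
            M = np.column_stack([x, np.ones_like(x)])
            (A, _b), *_ = np.linalg.lstsq(M, y, rcond=None)
        resid = y - M @ [A, _b]
        return float(A), float(np.sum(resid ** 2)), delta[sel], resid, int(sel.sum())

    r = _fit_at(ci0)
    if r is None:
        raise ValueError("not enough post-contact samples to fit")
    A, _sse, deltas, resid, n_fit = r
    ci = ci0
    z0 = float(z[ci])
    E = A / model.prefactor
    if E <= 0:
        raise ValueError(
            f"fitted modulus is non-positive (A={A:.3e}); check contact point "
            f"at index {ci} and baseline drift")
    return ModulusFit(E=E, contact_index=int(ci), contact_z=z0,
                      fit_range=(float(deltas.min()), float(deltas.max())),
                      residual_rms=float(np.sqrt(np.mean(resid ** 2))),
                      n_fit=n_fit)


def grid_summary(fits, layout=None):
    """Summarize modulus fits sampled on gel grids.

    ``fits`` is an iterable of dicts with keys ``gel``, ``area`` and either
    ``E`` (Pa) or ``error`` (a failed fit).  Returns a dict with per-area
    mean +/- sd, per-gel means of area means, and failure counts.
    """
    import pandas as pd

    rows = list(fits)
    df = pd.DataFrame(rows)
    if "E" not in df.columns:
        df["E"] = np.nan
    ok = df[df["E"].notna()]
    failures = df["E"].isna().groupby([df["gel"], df["area"]]).sum()
    per_area = ok.groupby(["gel", "area"])["E"].agg(["mean", "std", "count"])
    per_gel = per_area["mean"].groupby(level="gel").mean()
    return {
        "per_area": per_area,
        "per_gel": per_gel,
        "n_failed": int(df["E"].isna().sum()),
        "failures_by_area": failures,
    }
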