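"""Current-ratio steering and the return-electrode / balancing experiments.

The steering indexes split a fixed per-plane total current between the two
stimulating channels of each plane:

    alphaX = I1 / (I1 + I2)     (nasal / temporal, horizontal plane)
    alphaY = I3 / (I3 + I4)     (superior / inferior, vertical plane)

alphaX = alphaY = 0.5 drives all channels equally.  Because the conduction
problem is linear, a single set of unit-current lead fields per montage
supports the whole (alphaX, alphaY) grid by superposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .envelope import _mmea_closed_form, mmea_min_approx
from .fem import FieldSampler, LeadFieldSolver
from .geometry import (EyeModelParams, LabeledMesh, MeshSpec,
                       _attach_electrodes, build_eye_model, montage_2d,
                       montage_3d)
from .retina import (PROFILE_MERIDIANS, FocalityStats, ProfileCurve,
                     RetinalSampleGrid, Width, central_peak, chord_width,
                     contour_80, peak_enface, profile_points,
                     profile_through_point, width_at_fraction)

DIRECTIONS = ("horizontal", "vertical", "diagonal")
EDGE_MERIDIANS = np.arange(0.0, 360.0, 45.0)


@dataclass(frozen=True)
class MontageConfig:
    theta1H: float
    theta2H: float
    theta1V: Optional[float] = None
    theta2V: Optional[float] = None
    montage_kind: str = "3D"

    def __post_init__(self):
        if not (0.0 < self.theta1H < self.theta2H < 180.0):
            raise ValueError("require 0 < theta1 < theta2 < 180")
        if self.montage_kind not in ("2D", "3D"):
            raise ValueError(f"unknown montage kind {self.montage_kind!r}")

    def electrodes(self):
        if self.montage_kind == "2D":
            return montage_2d(self.theta1H, self.theta2H)
        return montage_3d(self.theta1H, self.theta2H,
                          self.theta1V, self.theta2V)


@dataclass(frozen=True)
class CurrentRatios:
    alphaX: float = 0.5
    alphaY: float = 0.5
    total_per_plane: float = 2.0       # mA; I1+I2 and I3+I4

    def __post_init__(self):
        if not (0.0 <= self.alphaX <= 1.0 and 0.0 <= self.alphaY <= 1.0):
            raise ValueError("current ratios must lie in [0, 1]")
        if self.total_per_plane <= 0:
            raise ValueError("total per-plane current must be positive")


def currents_from_ratios(r: CurrentRatios, montage_kind: str = "3D"
                         ) -> Dict[int, float]:
    """Channel currents (mA): I1 = aX*T, I2 = (1-aX)*T, I3/I4 likewise."""
    T = r.total_per_plane
    out = {1: r.alphaX * T, 2: (1.0 - r.alphaX) * T}
    if montage_kind == "3D":
        out[3] = r.alphaY * T
        out[4] = (1.0 - r.alphaY) * T
    return out


# ---------------------------------------------------------------------------
# Experiment context: one mesh, one factorization, cached channel solves
# ---------------------------------------------------------------------------

@dataclass
class CaseResult:
    """Metrics of one (montage, current-ratio) configuration."""

    ratios: Optional[CurrentRatios]
    stats: FocalityStats
    grid_values: np.ndarray                    # (Ne, Nm) normalized MMEA
    profiles: Dict[str, ProfileCurve]
    center_value: float                        # raw MMEA at the pole
    edge_values: np.ndarray                    # raw MMEA at 8 edge points
    excluded: bool = False
    exclusion_reason: str = ""


class TIExperiment:
    """Shared context for all montage experiments on one eye model.

    Builds the labeled mesh once, factorizes the stiffness matrix once,
    caches per-channel unit-current solves (keyed by electrode geometry),
    and samples channel fields on the retinal metric point sets.
    """

    def __init__(self, params: Optional[EyeModelParams] = None,
                 mesh_spec: Optional[MeshSpec] = None,
                 include_nerve: bool = True,
                 ecc_step: float = 1.0, meridian_step: float = 2.0,
                 extent: float = 80.0, profile_step: float = 0.25):
        self.params = params or EyeModelParams()
        self.mesh_spec = mesh_spec or MeshSpec()
        self.mesh = build_eye_model(self.params, (), self.mesh_spec,
                                    include_nerve=include_nerve)
        self.solver = LeadFieldSolver(self.mesh)
        self.sampler = FieldSampler(self.mesh)

        self._profile_step = profile_step
        self.grid = RetinalSampleGrid.build(self.params, ecc_step,
                                            meridian_step, extent)
        pts = [self.grid.points()]
        self._slices = {"grid": slice(0, len(pts[0]))}
        self.profile_abscissa: Dict[str, np.ndarray] = {}
        off = len(pts[0])
        for d in DIRECTIONS:
            t, p = profile_points(d, self.params.retina_mid_radius, extent,
                                  profile_step)
            self.profile_abscissa[d] = t
            self._slices[d] = slice(off, off + len(p))
            pts.append(p)
            off += len(p)
        # retinal center + 8 edge points at the extent boundary
        from .retina import retinal_point
        ce = [retinal_point(0.0, 0.0, self.params.retina_mid_radius)]
        ce += [retinal_point(extent, m, self.params.retina_mid_radius)
               for m in EDGE_MERIDIANS]
        self._slices["center_edge"] = slice(off, off + len(ce))
        pts.append(np.vstack(ce))
        self.points = np.vstack(pts)
        self._channel_cache: Dict[tuple, np.ndarray] = {}
        self.n_solves = 0

    # -- lead fields --------------------------------------------------------
    def _channel_key(self, montage, channel_id) -> tuple:
        els = sorted((e.role, e.plane, e.side, e.theta, e.diameter_um)
                     for e in montage if e.channel_id == channel_id)
        return tuple(els)

    def unit_fields(self, montage) -> Dict[int, np.ndarray]:
        """Unit-current (1 mA) channel E-fields at all metric points.

        Solves are cached per channel electrode geometry, so a
        return-electrode sweep or a balancing search only pays for the
        channels that actually moved.
        """
        chans = sorted({e.channel_id for e in montage})
        out = {}
        missing = [c for c in chans
                   if self._channel_key(montage, c) not in self._channel_cache]
        if missing:
            _attach_electrodes(self.mesh, montage, self.mesh_spec)
            for c in missing:
                _phi, E = self.solver.solve_channel(c)
                self.n_solves += 1
                samp = self.sampler.sample(E, self.points)
                self._channel_cache[self._channel_key(montage, c)] = samp
        for c in chans:
            out[c] = self._channel_cache[self._channel_key(montage, c)]
        return out

    # -- metrics ------------------------------------------------------------
    def _raw_mmea(self, unit: Dict[int, np.ndarray],
                  currents: Dict[int, float], kind: str) -> np.ndarray:
        scaled = [currents[c] * unit[c] for c in sorted(currents)]
        if kind == "2D":
            return _mmea_closed_form(scaled[0], scaled[1])
        return np.asarray(mmea_min_approx(scaled))

    def case(self, montage_kind: str, unit: Dict[int, np.ndarray],
             currents: Dict[int, float],
             ratios: Optional[CurrentRatios] = None) -> CaseResult:
        raw = self._raw_mmea(unit, currents, montage_kind)
        g = raw[self._slices["grid"]]
        lo, hi = float(g.min()), float(g.max())
        span = max(hi - lo, 1e-300)
        grid_values = ((g - lo) / span).reshape(self.grid.shape())

        stats = FocalityStats()
        profiles = {}
        # focality stats are measured on curves through the convergent
        # peak: the peak abscissa is then the central-peak offset relative
        # to the retinal center, and widths characterize the convergent
        # area whichever direction it was steered in
        peak_ab = peak_enface(self.grid, grid_values)
        for d in DIRECTIONS:
            # center-line curves (map display convention) kept for export
            vals = (raw[self._slices[d]] - lo) / span
            profiles[d] = ProfileCurve(d, self.profile_abscissa[d], vals)
            curve = profile_through_point(self.grid, grid_values, d,
                                          peak_ab, step=self._profile_step)
            try:
                _pv, po, _tie = central_peak(curve)
                stats.central_peak_value[d] = hi
                stats.central_peak_offset[d] = po
                stats.fwhm[d] = width_at_fraction(curve, 0.5)
                stats.width80[d] = width_at_fraction(curve, 0.8)
            except ValueError:
                pass
            chord = chord_width(curve, 0.8)
            if chord is not None:
                stats.chord80[d] = chord
        closed, overlap, _comp = contour_80(self.grid, grid_values)
        stats.contour_closed = closed
        stats.nerve_overlap = overlap

        ce = raw[self._slices["center_edge"]]
        excluded = (not closed) or (overlap != "none")
        reason = ("unclosed contour" if not closed
                  else f"nerve overlap ({overlap})" if overlap != "none"
                  else "")
        return CaseResult(ratios=ratios, stats=stats, grid_values=grid_values,
                          profiles=profiles, center_value=float(ce[0]),
                          edge_values=ce[1:], excluded=excluded,
                          exclusion_reason=reason)

    def run_case(self, montage: MontageConfig,
                 ratios: Optional[CurrentRatios] = None) -> CaseResult:
        ratios = ratios or CurrentRatios()
        unit = self.unit_fields(montage.electrodes())
        currents = currents_from_ratios(ratios, montage.montage_kind)
        return self.case(montage.montage_kind, unit, currents, ratios)


# ---------------------------------------------------------------------------
# Experiment drivers
# ---------------------------------------------------------------------------

def run_return_sweep(exp: TIExperiment, theta2_list: Sequence[float],
                     montage_kind: str = "3D", theta1: float = 30.0
                     ) -> Dict[float, CaseResult]:
    """Equal-current sweep over return-electrode angles theta2."""
    out = {}
    for th2 in theta2_list:
        cfg = MontageConfig(theta1H=theta1, theta2H=th2,
                            theta1V=theta1, theta2V=th2,
                            montage_kind=montage_kind)
        out[float(th2)] = exp.run_case(cfg)
    return out


def convergence_onset(sweep: Dict[float, CaseResult]) -> float:
    """Largest theta2 at which the central MMEA has not yet surpassed every
    edge value (the onset threshold of central convergence)."""
    below = [t for t, c in sorted(sweep.items())
             if c.center_value <= c.edge_values.max()]
    if not below:
        raise ValueError("central point exceeds edges over the whole sweep")
    return float(max(below))


def balance_vertical_montage(exp: TIExperiment, theta2H: float,
                             window: Tuple[float, float] = (-4.0, 8.0),
                             step: float = 1.0,
                             theta1: float = 30.0,
                             refine_step: Optional[float] = None) -> float:
    """theta2V equalizing horizontal and vertical 80% widths (equal currents).

    Searches a grid over ``theta2H + window``, minimizing
    |width80_h - width80_v|; deterministic tie-break toward smaller theta2V.
    """
    def objective(th2v: float) -> float:
        cfg = MontageConfig(theta1H=theta1, theta2H=theta2H,
                            theta1V=theta1, theta2V=th2v, montage_kind="3D")
        case = exp.run_case(cfg)
        wh = case.stats.width80.get("horizontal")
        wv = case.stats.width80.get("vertical")
        if wh is None or wv is None or wh.censored or wv.censored:
            return np.inf
        return abs(wh.width - wv.width)

    lo, hi = theta2H + window[0], theta2H + window[1]
    cand = np.arange(lo, hi + 0.5 * step, step)
    vals = np.array([objective(t) for t in cand])
    if not np.isfinite(vals).any():
        raise RuntimeError("no convergent field at any candidate theta2V")
    best = float(cand[int(np.argmin(vals))])     # argmin takes first tie
    if refine_step:
        cand2 = np.arange(best - step, best + step + 0.5 * refine_step,
                          refine_step)
        vals2 = np.array([objective(t) for t in cand2])
        best = float(cand2[int(np.argmin(vals2))])
    return best


@dataclass
class SteeringReport:
    """(alphaX, alphaY) grid results with exclusion bookkeeping."""

    montage: MontageConfig
    cases: List[CaseResult]
    summaries: Dict[str, Dict[str, float]] = field(default_factory=dict)

    @property
    def included(self) -> List[CaseResult]:
        return [c for c in self.cases if not c.excluded]

    @property
    def excluded(self) -> List[CaseResult]:
        return [c for c in self.cases if c.excluded]

    def summarize(self) -> Dict[str, Dict[str, float]]:
        """Per-direction mean +/- SD of the 80% width and offset ranges over
        the non-excluded grid cases.

        Widths are measured on curves through each case's convergent peak,
        so they characterize the steered area itself.
        """
        out = {}
        for d in DIRECTIONS:
            widths = [c.stats.width80[d].width for c in self.included
                      if d in c.stats.width80
                      and not c.stats.width80[d].censored]
            offsets = [c.stats.central_peak_offset[d] for c in self.included
                       if d in c.stats.central_peak_offset]
            entry: Dict[str, float] = {}
            if widths:
                entry["width80_mean"] = float(np.mean(widths))
                entry["width80_sd"] = float(np.std(widths, ddof=1)) \
                    if len(widths) > 1 else 0.0
            if offsets:
                entry["offset_min"] = float(np.min(offsets))
                entry["offset_max"] = float(np.max(offsets))
            out[d] = entry
        self.summaries = out
        return out


def run_steering_grid(exp: TIExperiment, montage: MontageConfig,
                      alphas: Optional[Sequence[float]] = None,
                      total_per_plane: float = 2.0) -> SteeringReport:
    """Sweep (alphaX, alphaY) by superposition; 4 lead solves total."""
    if alphas is None:
        alphas = (0.1, 0.3, 0.5, 0.7, 0.9)
    unit = exp.unit_fields(montage.electrodes())
    cases = []
    for aX in alphas:
        for aY in (alphas if montage.montage_kind == "3D" else (0.5,)):
            r = CurrentRatios(alphaX=float(aX), alphaY=float(aY),
                              total_per_plane=total_per_plane)
            currents = currents_from_ratios(r, montage.montage_kind)
            cases.append(exp.case(montage.montage_kind, unit, currents, r))
    report = SteeringReport(montage=montage, cases=cases)
    report.summarize()
    return report
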