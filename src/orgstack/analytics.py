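"""Assay-level analytics: survival, chemosensitivity, staining grids, stats.

The core drug-response readouts compare a well at treatment start (d0)
against the same well some days later (dN):

* survival rate, % of d0 — surviving object count relative to the count at
  treatment start;
* size-change ratio, % — total cross-sectional area at dN relative to d0,
  the statistic thresholded to call a line chemo-sensitive or resistant.

The default sensitivity cutoff of 36.42% on the size-change ratio is taken
as a configured constant (it was derived from patient-outcome ROC analysis
elsewhere, not from imaging data); a ratio below the cutoff is called
sensitive, with the boundary itself assigned to resistant.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .errors import InvalidParameterError
from .quantify import (DEFAULT_GREEN_THRESHOLD, WellSummary, labeling_rate,
                       records_from_scene)

__all__ = [
    "TimepointPair",
    "ChemoCall",
    "DEFAULT_CUTOFF",
    "survival_rate",
    "size_change_ratio",
    "classify_chemosensitivity",
    "staining_grid",
    "survival_recovery_experiment",
    "compare_groups",
]

DEFAULT_CUTOFF = 36.42  # % size-change ratio separating sensitive from resistant

_STAR_LEVELS = ((1e-4, "****"), (1e-3, "***"), (0.05, "*"))


@dataclass(frozen=True)
class TimepointPair:
    """Summaries of the same well at treatment start (d0) and day ``day``."""

    d0: WellSummary
    dN: WellSummary
    day: int = 10

    def __post_init__(self) -> None:
        if self.day <= 0:
            raise InvalidParameterError("day must be > 0")


@dataclass(frozen=True)
class ChemoCall:
    """A chemosensitivity call for one organoid line/well."""

    size_change_ratio: float  # %
    cutoff: float  # %
    call: str  # "sensitive" | "resistant"


def survival_rate(pair: TimepointPair) -> float:
    """Surviving objects at dN as a percentage of the d0 count.

    Can exceed 100% when new organoids formed after d0.
    """
    if pair.d0.n_objects == 0:
        raise ZeroDivisionError(
            "survival rate is undefined: the d0 well has no objects")
    return 100.0 * pair.dN.n_objects / pair.d0.n_objects


def size_change_ratio(pair: TimepointPair, relative_change: bool = False) -> float:
    """Total-area ratio dN/d0 in percent.

    With ``relative_change=True`` returns the percent *change*
    ``100 (dN - d0)/d0`` instead of the ratio (an alternative reading of
    "size change"; the ratio is the primary definition here).
    """
    if pair.d0.total_area <= 0:
        raise ZeroDivisionError(
            "size-change ratio is undefined: the d0 well has no measured area")
    ratio = 100.0 * pair.dN.total_area / pair.d0.total_area
    return ratio - 100.0 if relative_change else ratio


def classify_chemosensitivity(ratio: float, cutoff: float = DEFAULT_CUTOFF) -> ChemoCall:
    """Call a line sensitive (ratio < cutoff) or resistant (ratio >= cutoff).

    Growth suppressed below the cutoff means the treatment worked; the
    boundary itself is conservatively assigned to resistant.
    """
    if ratio < 0:
        raise InvalidParameterError(f"ratio must be >= 0, got {ratio}")
    if cutoff < 0:
        raise InvalidParameterError(f"cutoff must be >= 0, got {cutoff}")
    call = "sensitive" if ratio < cutoff else "resistant"
    return ChemoCall(size_change_ratio=float(ratio), cutoff=float(cutoff), call=call)


def staining_grid(concentrations, times, model=None, n_organoids: int = 200,
                  seed: int = 0,
                  green_threshold: float = DEFAULT_GREEN_THRESHOLD) -> pd.DataFrame:
    """Simulated labeling rate (%) for every concentration x time cell.

    Each cell stains the same well of ``n_organoids`` fully live organoids
    under the kinetics model with that cell's dose and time, then scores the
    labeling rate at the default intensity cutoff.  The uniform draws behind
    the labeling decisions are shared across cells (common random numbers),
    so the observed grid is monotone in dose and time whenever the model's
    labeling probability is — not just in expectation.  Returns a DataFrame
    indexed by concentration (µM) with staining times (min) as columns.
    """
    from .scene import StainingModel, apply_staining, generate_scene

    if model is None:
        model = StainingModel()
    concentrations = list(concentrations)
    times = list(times)
    if not concentrations or not times:
        raise InvalidParameterError("concentration and time grids must be non-empty")
    if n_organoids < 1:
        raise InvalidParameterError("n_organoids must be >= 1")

    scene = generate_scene(n_organoids, 50.0, seed=seed)
    grid = np.zeros((len(concentrations), len(times)))
    for i, c in enumerate(concentrations):
        for j, t in enumerate(times):
            stained = apply_staining(
                scene, replace(model, concentration=float(c), time=float(t)),
                seed=seed)
            grid[i, j] = labeling_rate(records_from_scene(stained),
                                       green_threshold)
    return pd.DataFrame(grid, index=pd.Index(concentrations, name="concentration_uM"),
                        columns=pd.Index(times, name="time_min"))


def survival_recovery_experiment(
    kill_fraction: float,
    n_objects: int = 200,
    per_field: int = 8,
    diameter=(40.0, 80.0),
    seed: int = 0,
    n_layers: int = 7,
    gel_depth: float = 1100.0,
    xy_extent: tuple[float, float] = (512.0, 512.0),
) -> dict:
    """Measure how well the full pipeline recovers a simulated kill fraction.

    Plants ``n_objects`` organoids across fields of ``per_field``, images and
    counts each well on the live channel at d0, applies a treatment killing
    ``kill_fraction`` of objects (binomially), restains, re-images and counts
    again, and reports:

    * ``recovered`` — end-to-end survival, 100 x dN count / d0 count (%);
    * ``realized`` — ground-truth survivor percentage of the simulated wells
      (binomial realization of ``1 - kill_fraction``);
    * ``nominal`` — 100 x (1 - kill_fraction).

    ``recovered - realized`` isolates detection/segmentation error;
    ``realized - nominal`` is pure binomial sampling noise.
    """
    from .acquisition import plan_zstack
    from .edf import fuse_stack
    from .quantify import segment_objects
    from .scene import (StainingModel, TreatmentEffect, apply_staining,
                        apply_treatment, generate_scene, render_stack)

    if n_objects < per_field or per_field < 1:
        raise InvalidParameterError("need n_objects >= per_field >= 1")
    plan = plan_zstack(gel_depth, n_layers)
    staining = StainingModel(cu_concentration=0.1)
    effect = TreatmentEffect(kill_fraction=kill_fraction)
    margin = (max(diameter) if np.iterable(diameter) else diameter) / 2.0 + 10.0
    rng = np.random.default_rng(seed)
    d0_count = dn_count = survivors = total = 0
    n_fields = int(np.ceil(n_objects / per_field))
    for _ in range(n_fields):
        n_here = min(per_field, n_objects - total)
        s_scene, s_d0, s_kill, s_dn = (int(rng.integers(0, 2**31 - 1))
                                       for _ in range(4))
        scene = generate_scene(n_here, diameter, gel_depth, xy_extent,
                               seed=s_scene, xy_margin=margin)
        d0 = apply_staining(scene, staining, seed=s_d0)
        comp0 = fuse_stack(render_stack(d0, plan, staining=staining, seed=s_d0))
        _, rec0 = segment_objects(comp0, channel="green")
        treated = apply_treatment(scene, effect, seed=s_kill)
        survivors += sum(1 for o in treated.objects if o.live_fraction > 0)
        dn = apply_staining(treated, staining, seed=s_dn)
        compn = fuse_stack(render_stack(dn, plan, staining=staining, seed=s_dn))
        _, recn = segment_objects(compn, channel="green")
        d0_count += len(rec0)
        dn_count += len(recn)
        total += n_here
    recovered = 100.0 * dn_count / d0_count
    return {
        "recovered": recovered,
        "realized": 100.0 * survivors / total,
        "nominal": 100.0 * (1.0 - kill_fraction),
        "n_objects": total,
        "d0_detected": d0_count,
        "dN_detected": dn_count,
    }


def _stars(p: float) -> str:
    for level, mark in _STAR_LEVELS:
        if p < level:
            return mark
    return "ns"


def _metric_values(group, metric: str) -> np.ndarray:
    values = []
    for item in group:
        if metric == "survival_rate":
            if not isinstance(item, TimepointPair):
                raise InvalidParameterError(
                    "survival_rate comparisons need TimepointPair wells")
            values.append(survival_rate(item))
        elif metric == "total_area":
            summary = item.dN if isinstance(item, TimepointPair) else item
            values.append(summary.total_area)
        elif metric == "n_objects":
            summary = item.dN if isinstance(item, TimepointPair) else item
            values.append(float(summary.n_objects))
        else:
            raise InvalidParameterError(f"unknown metric {metric!r}")
    return np.asarray(values, dtype=float)


def compare_groups(control, treated_groups: dict, metric: str = "survival_rate",
                   error: str = "sd") -> pd.DataFrame:
    """Treated-vs-control comparison with two-tailed Student's t tests.

    ``control`` and each value of ``treated_groups`` is a list of wells
    (:class:`WellSummary` or :class:`TimepointPair`, at least two per
    group).  Returns one row per group with n, mean, SD, SEM, the two-tailed
    t-test p-value against control (unadjusted pairwise tests) and the
    conventional star annotation (* p<0.05, *** p<0.001, **** p<0.0001).
    """
    if error not in ("sd", "sem"):
        raise InvalidParameterError("error must be 'sd' or 'sem'")
    groups = {"control": list(control), **{k: list(v) for k, v in treated_groups.items()}}
    for name, wells in groups.items():
        if len(wells) < 2:
            raise InvalidParameterError(
                f"group {name!r} has {len(wells)} wells; need >= 2 for a variance")
    ctrl = _metric_values(groups["control"], metric)
    rows = []
    for name, wells in groups.items():
        vals = _metric_values(wells, metric)
        if name == "control":
            p = np.nan
        else:
            p = float(sstats.ttest_ind(vals, ctrl).pvalue)
        rows.append({
            "group": name,
            "n": len(vals),
            "mean": float(np.mean(vals)),
            "sd": float(np.std(vals, ddof=1)),
            "sem": float(sstats.sem(vals)),
            "error_shown": error,
            "p_value": p,
            "stars": "" if name == "control" else _stars(p),
        })
    return pd.DataFrame(rows).set_index("group")
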