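"""Module-eigengene stage trajectories and cross-model agreement.

Each module's eigengene is summarised per disease model as a three-point
trajectory (mean ME over the samples of the control, early and late stage
groups; the control group is shared, so its value is identical across
models).  Pearson correlation of these trajectories between model pairs
quantifies shared regulation: modules with R above a threshold in at least
one model pair (default; a strict all-pairs mode exists) are flagged as
shared, and modules whose averaged R exceeds a higher highlight threshold
are the headline co-regulated modules.  Direction (up/down/flat) is the sign
of the mean late-minus-control change across models.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .simulate import MODELS, SHARED

STAGE_ORDER = ("control", "early", "late")
PAIRS = tuple(combinations(MODELS, 2))  # (aging,noise), (aging,cisplatin), (noise,cisplatin)
_PAIR_COLS = {
    ("aging", "noise"): "R_aging_noise",
    ("aging", "cisplatin"): "R_aging_cisplatin",
    ("noise", "cisplatin"): "R_noise_cisplatin",
}


@dataclass
class TrajectorySet:
    """Per (module, model) ordered stage means of the module eigengene.

    ``n_samples`` (the number of samples the eigengene was computed over)
    sets the scale of a unit-norm eigengene and hence the default
    flat-trajectory guard; it is None for hand-built toy sets.
    """

    values: pd.DataFrame  # MultiIndex (module, model) x stage columns
    n_samples: int | None = None

    def trajectory(self, module: str, model: str) -> np.ndarray:
        return self.values.loc[(module, model), list(STAGE_ORDER)].to_numpy(float)

    def modules(self) -> list[str]:
        return list(self.values.index.get_level_values("module").unique())

    def default_min_amplitude(self) -> float:
        """Half a typical sample value of a unit-norm eigengene, 0.5/sqrt(n).

        A stage trajectory whose total excursion stays below this carries no
        real stage signal — its three points are eigengene noise — so its
        Pearson correlations are meaningless and get the undefined flag.
        Hand-built sets without ``n_samples`` get no guard (0.0).
        """
        if self.n_samples is None:
            return 0.0
        return 0.5 / np.sqrt(self.n_samples)


def stage_trajectories(me: pd.DataFrame, design: pd.DataFrame) -> TrajectorySet:
    """Average the ME over each (model, stage) group; reuse controls everywhere.

    ``me`` is the module x sample eigengene matrix; ``design`` the sample
    table.  Raises when any (model, stage) group has no samples.
    """
    design = design.set_index("sample_id")
    missing = [s for s in me.columns if s not in design.index]
    if missing:
        raise ValidationError(f"samples without design rows: {missing[:3]}")
    ctrl_samples = design.index[(design["stage"] == "control")]
    rows, index = [], []
    for module in me.index:
        for model in MODELS:
            vals = []
            for stage in STAGE_ORDER:
                if stage == "control":
                    samp = ctrl_samples
                else:
                    samp = design.index[
                        (design["model"] == model) & (design["stage"] == stage)
                    ]
                if len(samp) == 0:
                    raise ValidationError(f"empty group ({model}, {stage})")
                vals.append(float(me.loc[module, list(samp)].mean()))
            rows.append(vals)
            index.append((module, model))
    idx = pd.MultiIndex.from_tuples(index, names=["module", "model"])
    return TrajectorySet(
        pd.DataFrame(rows, index=idx, columns=list(STAGE_ORDER)),
        n_samples=me.shape[1],
    )


def _pearson3(a: np.ndarray, b: np.ndarray,
              min_amplitude: float = 0.0) -> tuple[float, bool]:
    """Pearson R of two short trajectories; (0.0, True) flags a flat input.

    A trajectory is flat when its total excursion (max - min) does not
    exceed ``min_amplitude``; zero variance is the ``min_amplitude = 0``
    special case.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if (a.max() - a.min()) <= min_amplitude or (b.max() - b.min()) <= min_amplitude:
        return 0.0, True
    return float(np.corrcoef(a, b)[0, 1]), False


def pairwise_trajectory_correlation(
    t: TrajectorySet, module: str, min_amplitude: float = 0.0
) -> tuple[dict[tuple[str, str], float], dict[tuple[str, str], bool]]:
    """Pearson R of the module's trajectories for each of the 3 model pairs.

    Returns ``(r_by_pair, undefined_flags)``; an undefined R (a flat
    trajectory over the 3 points) is reported as 0 with its flag set, never
    silently dropped.  The default ``min_amplitude = 0`` flags only exact
    zero variance, keeping R invariant to positive affine rescaling.
    """
    rs, flags = {}, {}
    for pair in PAIRS:
        r, undef = _pearson3(t.trajectory(module, pair[0]),
                             t.trajectory(module, pair[1]),
                             min_amplitude=min_amplitude)
        rs[pair] = r
        flags[pair] = undef
    return rs, flags


def classify_direction(t: TrajectorySet, module: str,
                       flat_tol: float = 0.0) -> str:
    """up/down/flat from the mean late-minus-control change across models."""
    delta = float(
        np.mean([t.trajectory(module, m)[2] - t.trajectory(module, m)[0]
                 for m in MODELS])
    )
    if delta > flat_tol:
        return "up"
    if delta < -flat_tol:
        return "down"
    return "flat"


def trajectory_correlation_report(
    t: TrajectorySet,
    flat_tol: float = 0.0,
    min_amplitude: float | None = None,
) -> pd.DataFrame:
    """Raw per-module agreement table: pairwise R, averaged R, direction.

    The average runs over the defined pairwise values only; a module whose
    three correlations are all undefined gets R_avg = 0 with
    ``undefined_pairs = 3``.  ``min_amplitude`` (default: the set's
    scale-aware guard, 0.5/sqrt(n_samples)) flags pairs involving an
    effectively flat trajectory as undefined, so noise-only trajectories
    cannot produce spuriously high correlations.
    """
    if min_amplitude is None:
        min_amplitude = t.default_min_amplitude()
    rows = []
    for module in t.modules():
        rs, flags = pairwise_trajectory_correlation(
            t, module, min_amplitude=min_amplitude
        )
        defined = [rs[p] for p in PAIRS if not flags[p]]
        row = {"module": module}
        row.update({_PAIR_COLS[p]: rs[p] for p in PAIRS})
        row.update({_PAIR_COLS[p] + "_defined": not flags[p] for p in PAIRS})
        row["undefined_pairs"] = sum(flags.values())
        row["R_avg"] = float(np.mean(defined)) if defined else 0.0
        row["direction"] = classify_direction(t, module, flat_tol=flat_tol)
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=["module", *(_PAIR_COLS[p] for p in PAIRS),
                 *(_PAIR_COLS[p] + "_defined" for p in PAIRS),
                 "undefined_pairs", "R_avg", "direction"],
    )


def select_shared_modules(
    report: pd.DataFrame,
    r_threshold: float = 0.85,
    min_pairs: int = 1,
    avg_highlight: float = 0.92,
) -> pd.DataFrame:
    """Apply the shared-module rules and rank by averaged R (descending).

    A module is ``selected`` when at least ``min_pairs`` of its three
    pairwise correlations exceed ``r_threshold`` (default 1 pair, reading
    "R above threshold in any two of the three models" as at least one model
    *pair*; ``min_pairs=3`` is the strict all-pairs mode).  ``highlighted``
    requires averaged R above ``avg_highlight``.
    """
    for name, val in (("r_threshold", r_threshold),
                      ("avg_highlight", avg_highlight)):
        if not -1.0 <= val <= 1.0:
            raise ConfigError(f"{name} must lie in [-1, 1]")
    if not 1 <= min_pairs <= 3:
        raise ConfigError("min_pairs must be 1, 2 or 3")
    rep = report.copy()
    # undefined pairs are stored as R = 0 and never count as passing
    n_pass = sum(
        ((rep[_PAIR_COLS[p]] > r_threshold) & rep[_PAIR_COLS[p] + "_defined"])
        for p in PAIRS
    )
    rep["selected"] = n_pass >= min_pairs
    rep["highlighted"] = rep["R_avg"] > avg_highlight
    rep = rep.sort_values("R_avg", ascending=False, kind="stable")
    return rep.reset_index(drop=True)


def shared_module_report(
    t: TrajectorySet,
    r_threshold: float = 0.85,
    min_pairs: int = 1,
    avg_highlight: float = 0.92,
    flat_tol: float = 0.0,
    min_amplitude: float | None = None,
) -> pd.DataFrame:
    """Convenience wrapper: build the raw report and apply the selection."""
    return select_shared_modules(
        trajectory_correlation_report(t, flat_tol=flat_tol,
                                      min_amplitude=min_amplitude),
        r_threshold=r_threshold,
        min_pairs=min_pairs,
        avg_highlight=avg_highlight,
    )
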