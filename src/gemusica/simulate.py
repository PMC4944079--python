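"""Synthetic expression matrices with stem-cell-like group structure.

The generator emulates the cohort layout the analysis assumes: several cell
populations (e.g. embryonic, neuronal, mesenchymal stem cells, endothelial
cells) profiled on an HG-U133A-sized array (22,283 probe sets), each with a
disjoint set of marker genes expressed several log2 units above baseline.
Values are Gaussian on the log2 scale (log-normal intensities), with a
probe-specific baseline shared by all samples — the dominant source of
positive inter-sample correlation on real arrays — plus group marker shifts
and independent per-sample noise.

A knockdown-style perturbation interpolates selected samples' marker values
toward another group's mean profile, modeling oncogene inhibition that
shifts a tumor's expression program between stem-cell phenotypes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .matrix import ExpressionMatrix

__all__ = ["SimulationSpec", "simulate_matrix", "simulate_knockdown", "DEFAULT_GROUPS"]

DEFAULT_GROUPS: tuple[tuple[str, int], ...] = (
    ("ESC", 3),
    ("NSC", 3),
    ("MSC", 3),
    ("EC", 3),
)


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of the synthetic cohort.

    n_probes : number of probe sets (default 22,283, HG-U133A size, so the
        5% variance filter yields 1114).
    groups : (label, n_samples) pairs.
    markers_per_group : disjoint marker probes per group (default 100).
    marker_effect : log2-units up-shift of a group's markers in its own
        samples (default +4).
    baseline_mean, baseline_sd : mean and probe-to-probe spread of the
        shared log2 baseline (defaults 7 and 1.5).
    noise_sd : per-sample Gaussian noise on the log2 scale (default 0.5).
    seed : generator seed; identical specs give identical matrices.
    """

    n_probes: int = 22_283
    groups: tuple[tuple[str, int], ...] = DEFAULT_GROUPS
    markers_per_group: int = 100
    marker_effect: float = 4.0
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple((str(g), int(k)) for g, k in self.groups))
        labels = [g for g, _ in self.groups]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate group labels")
        if not self.groups or any(k < 1 for _, k in self.groups):
            raise ValueError("each group needs at least one sample")
        if self.markers_per_group < 1:
            raise ValueError("markers_per_group must be >= 1")
        if self.n_probes < len(self.groups) * self.markers_per_group:
            raise ValueError("n_probes too small for disjoint marker sets")
        if self.noise_sd < 0 or self.baseline_sd < 0:
            raise ValueError("standard deviations must be non-negative")

    @property
    def n_samples(self) -> int:
        return sum(k for _, k in self.groups)


def _probe_ids(n: int) -> tuple[str, ...]:
    # HG-U133A-style identifiers
    return tuple(f"{200000 + i}_at" for i in range(n))


def simulate_matrix(
    spec: SimulationSpec,
) -> tuple[ExpressionMatrix, dict[str, str], dict[str, tuple[str, ...]]]:
    """Draw a cohort matrix; returns (matrix, sample->group labels, group->marker ids).

    Marker probes are assigned by a seeded draw without replacement, so the
    marker sets of different groups are disjoint.
    """
    rng = np.random.default_rng(spec.seed)
    probe_ids = _probe_ids(spec.n_probes)
    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, spec.n_probes)

    n_marked = len(spec.groups) * spec.markers_per_group
    marked = rng.choice(spec.n_probes, size=n_marked, replace=False)
    marker_rows: dict[str, np.ndarray] = {}
    marker_map: dict[str, tuple[str, ...]] = {}
    for gi, (label, _) in enumerate(spec.groups):
        rows = np.sort(marked[gi * spec.markers_per_group : (gi + 1) * spec.markers_per_group])
        marker_rows[label] = rows
        marker_map[label] = tuple(probe_ids[r] for r in rows)

    sample_ids: list[str] = []
    labels: dict[str, str] = {}
    columns: list[np.ndarray] = []
    for label, k in spec.groups:
        for r in range(1, k + 1):
            sid = f"{label}_{r}"
            sample_ids.append(sid)
            labels[sid] = label
            col = baseline + rng.normal(0.0, spec.noise_sd, spec.n_probes)
            col[marker_rows[label]] += spec.marker_effect
            columns.append(col)
    values = np.column_stack(columns)
    m = ExpressionMatrix(probe_ids, tuple(sample_ids), values, "log2")
    return m, labels, marker_map


def simulate_knockdown(
    m: ExpressionMatrix,
    labels: Mapping[str, str],
    marker_map: Mapping[str, Sequence[str]],
    source_group: str,
    target_group: str,
    shift_fraction: float,
    samples: Sequence[str] | None = None,
    seed: int | None = None,
) -> ExpressionMatrix:
    """Interpolate samples' marker profile toward another group's mean profile.

    For the selected ``samples`` (default: every sample of ``source_group``)
    the values at the union of source- and target-group marker probes are
    replaced by ``(1 - s) * x + s * target_mean`` with ``s = shift_fraction``;
    ``s = 0`` is the identity, ``s = 1`` pins markers at the target group's
    mean profile. The operation is deterministic; ``seed`` is accepted for
    interface stability and unused.
    """
    for g in (source_group, target_group):
        if g not in marker_map:
            raise KeyError(f"unknown group {g!r}")
    if not 0 <= shift_fraction <= 1:
        raise ValueError(f"shift_fraction must lie in [0, 1], got {shift_fraction}")
    if samples is None:
        samples = [s for s in m.sample_ids if labels.get(s) == source_group]
        if not samples:
            raise KeyError(f"no samples labeled {source_group!r}")
    unknown = [s for s in samples if s not in m.sample_ids]
    if unknown:
        raise KeyError(f"unknown sample(s): {unknown}")

    probe_index = {pid: i for i, pid in enumerate(m.probe_ids)}
    rows = sorted(
        {probe_index[p] for p in (*marker_map[source_group], *marker_map[target_group])}
    )
    target_cols = [j for j, s in enumerate(m.sample_ids) if labels.get(s) == target_group]
    if not target_cols:
        raise KeyError(f"no samples labeled {target_group!r} in matrix")
    target_mean = m.values[np.ix_(rows, target_cols)].mean(axis=1)

    values = m.values.copy()
    for sid in samples:
        j = m.sample_ids.index(sid)
        values[rows, j] = (1 - shift_fraction) * values[rows, j] + shift_fraction * target_mean
    return ExpressionMatrix(m.probe_ids, m.sample_ids, values, m.scale_tag)
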