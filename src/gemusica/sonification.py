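"""Transformation of expression values into melodies on an equal-tempered scale.

Each sample of a signature-restricted matrix becomes one melody: one note
per signature probe, in signature order, with pitch increasing monotonically
in log2 intensity so that high-pitched notes indicate highly expressed
genes. The default scale is the 88-key piano (A0 = 27.5 Hz, 12 keys per
octave); mapping bounds are calibrated globally over the whole analyzed
matrix so pitches are comparable across samples and cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np

from .matrix import ExpressionMatrix, IdentifierError

__all__ = [
    "ScaleConfig",
    "Note",
    "Melody",
    "DegenerateRangeError",
    "calibrate",
    "intensity_to_key",
    "key_to_frequency",
    "sonify_sample",
    "sonify_matrix",
    "write_note_table",
    "read_note_table",
    "write_score_text",
]

_VALID_MINDUR = (1, 2, 4, 8, 16, 32)


class DegenerateRangeError(ValueError):
    """All intensities equal: every note would collapse onto one key."""


@dataclass(frozen=True)
class ScaleConfig:
    """Sonification parameters.

    minfreq : lowest key frequency in Hz (default 27.5, piano A0).
    tonesteps : keys per octave (default 12, equal temperament).
    numkeys : number of keys (default 88).
    mindur : reciprocal note value for every note (8 = eighth note).
    maxNdots : maximum augmentation dots the score writer may use when
        merging tied repeats (merging itself is off by default).
    vol : velocity level; mapped to MIDI velocity as ``vol * 16`` clamped
        to [1, 127].
    meter : time signature as an (numerator, denominator) pair (default 4/4).
    """

    minfreq: float = 27.5
    tonesteps: int = 12
    numkeys: int = 88
    mindur: int = 8
    maxNdots: int = 2
    vol: int = 4
    meter: tuple[int, int] = (4, 4)

    def __post_init__(self) -> None:
        if self.minfreq <= 0:
            raise ValueError("minfreq must be positive")
        if self.tonesteps < 1 or self.numkeys < 2:
            raise ValueError("tonesteps must be >= 1 and numkeys >= 2")
        if self.mindur not in _VALID_MINDUR:
            raise ValueError(f"mindur must be one of {_VALID_MINDUR}")
        if self.maxNdots < 0 or self.vol < 1:
            raise ValueError("maxNdots must be >= 0 and vol >= 1")
        num, den = self.meter
        if num < 1 or den not in _VALID_MINDUR:
            raise ValueError(f"invalid meter {self.meter}")
        object.__setattr__(self, "meter", (int(num), int(den)))
        if not math.isfinite(self.maxfreq):
            raise ValueError("top-key frequency overflows")

    @property
    def maxfreq(self) -> float:
        return self.minfreq * 2.0 ** ((self.numkeys - 1) / self.tonesteps)

    @property
    def note_duration(self) -> Fraction:
        """Duration of every note as a fraction of a whole note."""
        return Fraction(1, self.mindur)

    @property
    def bar_length(self) -> Fraction:
        """Bar length as a fraction of a whole note."""
        return Fraction(*self.meter)

    @property
    def notes_per_bar(self) -> int:
        per_bar = self.bar_length / self.note_duration
        if per_bar.denominator != 1:
            raise ValueError("meter is not an integer multiple of the note duration")
        return int(per_bar)


@dataclass(frozen=True)
class Note:
    probe_id: str
    key_index: int
    frequency: float
    duration: Fraction
    velocity: int


@dataclass(frozen=True)
class Melody:
    """Ordered note sequence for one sample.

    ``calibration`` records the (lo, hi) log2-intensity bounds of the
    intensity-to-key map, shared by all melodies from one analysis.
    """

    sample_id: str
    notes: tuple[Note, ...]
    config: ScaleConfig
    calibration: tuple[float, float]

    def __len__(self) -> int:
        return len(self.notes)


def calibrate(m: ExpressionMatrix) -> tuple[float, float]:
    """Global (min, max) over all matrix entries — the pitch-map bounds.

    Bounds are global (all samples jointly), never per-sample, so a given
    pitch means the same intensity in every melody.
    """
    if m.values.size == 0:
        raise ValueError("cannot calibrate an empty matrix")
    lo = float(m.values.min())
    hi = float(m.values.max())
    if lo == hi:
        raise DegenerateRangeError(f"all intensities equal ({lo}); pitch range is degenerate")
    return lo, hi


def intensity_to_key(x: float, lo: float, hi: float, c: ScaleConfig) -> int:
    """Map a log2 intensity linearly onto a key index, half-up rounding.

    ``key = round((x - lo) / (hi - lo) * (numkeys - 1))`` clamped to
    [0, numkeys - 1]. Half-up rounding is fixed explicitly (0.5 always
    rounds toward the higher key) to avoid platform banker's-rounding drift.
    """
    if not lo < hi:
        raise DegenerateRangeError("calibration bounds must satisfy lo < hi")
    k = math.floor((x - lo) / (hi - lo) * (c.numkeys - 1) + 0.5)
    return min(max(k, 0), c.numkeys - 1)


def key_to_frequency(k: int, c: ScaleConfig) -> float:
    """Equal-temperament frequency of key ``k``: minfreq * 2**(k / tonesteps)."""
    if not 0 <= k <= c.numkeys - 1:
        raise ValueError(f"key index {k} outside [0, {c.numkeys - 1}]")
    return c.minfreq * 2.0 ** (k / c.tonesteps)


def _keys_for_column(col: np.ndarray, lo: float, hi: float, c: ScaleConfig) -> np.ndarray:
    k = np.floor((col - lo) / (hi - lo) * (c.numkeys - 1) + 0.5).astype(int)
    return np.clip(k, 0, c.numkeys - 1)


def sonify_sample(
    m: ExpressionMatrix,
    sample_id: str,
    c: ScaleConfig,
    calibration: tuple[float, float],
) -> Melody:
    """Build the melody for one sample of a signature-ordered matrix.

    One note per row, in row (= signature) order; all notes share the
    uniform duration 1/mindur and the velocity derived from ``vol``.
    """
    lo, hi = calibration
    if not lo < hi:
        raise DegenerateRangeError("calibration bounds must satisfy lo < hi")
    col = m.column(sample_id)
    keys = _keys_for_column(col, lo, hi, c)
    velocity = min(max(c.vol * 16, 1), 127)
    dur = c.note_duration
    notes = tuple(
        Note(pid, int(k), key_to_frequency(int(k), c), dur, velocity)
        for pid, k in zip(m.probe_ids, keys)
    )
    return Melody(sample_id, notes, c, (lo, hi))


def sonify_matrix(m: ExpressionMatrix, c: ScaleConfig | None = None) -> list[Melody]:
    """Sonify every sample of ``m`` under one global calibration."""
    c = c or ScaleConfig()
    cal = calibrate(m)
    return [sonify_sample(m, sid, c, cal) for sid in m.sample_ids]


# ---------------------------------------------------------------------------
# note table (CSV)

def write_note_table(mel: Melody, path: str | Path) -> None:
    """CSV note table: position, probe_id, key_index, frequency_hz, duration, velocity.

    The scale parameters and calibration are stored in ``#``-prefixed header
    comments so the file round-trips to an equal Melody.
    """
    c = mel.config
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(f"# sample_id={mel.sample_id}\n")
        fh.write(
            f"# minfreq={c.minfreq!r} tonesteps={c.tonesteps} numkeys={c.numkeys} "
            f"mindur={c.mindur} maxNdots={c.maxNdots} vol={c.vol} meter={c.meter[0]}/{c.meter[1]}\n"
        )
        fh.write(f"# calibration lo={mel.calibration[0]!r} hi={mel.calibration[1]!r}\n")
        fh.write("position,probe_id,key_index,frequency_hz,duration,velocity\n")
        for i, n in enumerate(mel.notes, start=1):
            fh.write(f"{i},{n.probe_id},{n.key_index},{n.frequency!r},{n.duration},{n.velocity}\n")


def read_note_table(path: str | Path) -> Melody:
    meta: dict[str, str] = {}
    notes: list[Note] = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# "):
                for tok in line[2:].replace("calibration ", "").split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        meta[k] = v
            elif line.startswith("position,"):
                continue
            elif line:
                pos, pid, key, freq, dur, vel = line.split(",")
                notes.append(Note(pid, int(key), float(freq), Fraction(dur), int(vel)))
    config = ScaleConfig(
        minfreq=float(meta["minfreq"]),
        tonesteps=int(meta["tonesteps"]),
        numkeys=int(meta["numkeys"]),
        mindur=int(meta["mindur"]),
        maxNdots=int(meta["maxNdots"]),
        vol=int(meta["vol"]),
        meter=tuple(int(x) for x in meta["meter"].split("/")),  # type: ignore[arg-type]
    )
    return Melody(meta["sample_id"], tuple(notes), config,
                  (float(meta["lo"]), float(meta["hi"])))


# ---------------------------------------------------------------------------
# plain-text score (LilyPond-compatible subset)

_PITCH_CLASSES = ["c", "cis", "d", "dis", "e", "f", "fis", "g", "gis", "a", "ais", "b"]


def _midi_pitch(note: Note, c: ScaleConfig) -> int:
    # anchored at A4 = 440 Hz = MIDI 69; exact 21 + key for the piano default
    return round(69 + 12 * math.log2(note.frequency / 440.0))


def _lily_pitch(midi: int) -> str:
    pc = _PITCH_CLASSES[midi % 12]
    octave = midi // 12 - 5  # 0 marks the small octave c..b (MIDI 48-59 bare)
    if octave >= 0:
        return pc + "'" * (octave + 1)
    return pc + "," * (-octave - 1)


def _lily_duration(base: int, dots: int) -> str:
    return str(base) + "." * dots


def _merge_run(length: int, mindur: int, max_dots: int) -> list[tuple[int, int]]:
    """Greedy split of a run of ``length`` repeated 1/mindur notes into
    (base, dots) durations, longest representable chunk first."""
    out: list[tuple[int, int]] = []
    remaining = length
    while remaining > 0:
        best = (mindur, 0, 1)  # base, dots, units consumed
        for a in range(int(math.log2(mindur)) + 1):
            for d in range(max_dots + 1):
                units = (1 << a) * (2 - Fraction(1, 1 << d))
                if units.denominator == 1 and units <= remaining and units > best[2]:
                    best = (mindur >> a, d, int(units))
        out.append((best[0], best[1]))
        remaining -= best[2]
    return out


def write_score_text(
    mel: Melody,
    path: str | Path,
    bars_from: int,
    bars_to: int,
    *,
    merge_repeats: bool = False,
) -> None:
    """Write a bar window of the melody as a plain-text (LilyPond subset) score.

    Bars are 1-indexed and inclusive; boundaries are found by accumulating
    note durations against the meter. Each note carries its probe id as a
    trailing comment. With ``merge_repeats`` enabled, consecutive notes of
    equal pitch inside a bar are merged into longer (possibly dotted, up to
    ``maxNdots`` dots) notes.
    """
    c = mel.config
    per_bar = c.notes_per_bar
    n_bars = math.ceil(len(mel.notes) / per_bar)
    if not 1 <= bars_from <= bars_to:
        raise ValueError(f"invalid bar range {bars_from}..{bars_to}")
    if bars_to > n_bars:
        raise ValueError(f"bar range {bars_from}..{bars_to} beyond melody ({n_bars} bars)")
    lines = [
        f"% sample {mel.sample_id}, bars {bars_from}-{bars_to}",
        f"\\time {c.meter[0]}/{c.meter[1]}",
        "{",
    ]
    for bar in range(bars_from, bars_to + 1):
        lines.append(f"  % bar {bar}")
        notes = mel.notes[(bar - 1) * per_bar : bar * per_bar]
        i = 0
        while i < len(notes):
            run = 1
            if merge_repeats:
                while i + run < len(notes) and notes[i + run].key_index == notes[i].key_index:
                    run += 1
            pitch = _lily_pitch(_midi_pitch(notes[i], c))
            probes = ",".join(n.probe_id for n in notes[i : i + run])
            if run == 1:
                lines.append(f"  {pitch}{c.mindur}  % {probes}")
            else:
                parts = " ~ ".join(
                    f"{pitch}{_lily_duration(b, d)}" for b, d in _merge_run(run, c.mindur, c.maxNdots)
                )
                lines.append(f"  {parts}  % {probes}")
            i += run
        lines.append("  |")
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
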