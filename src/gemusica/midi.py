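"""Minimal standard-MIDI-file (SMF format 0) writer for melodies.

Writes one track: a tempo event followed by a note-on/note-off pair per
note. Pitch is derived from each note's frequency relative to A4 = 440 Hz
(MIDI 69); under the default 88-key/27.5 Hz scale this is exactly
``21 + key_index`` (MIDI 21 = A0).
"""

from __future__ import annotations

import math
from pathlib import Path

from .sonification import Melody

__all__ = ["write_midi", "melody_midi_pitches", "TICKS_PER_QUARTER", "DEFAULT_TEMPO_BPM"]

TICKS_PER_QUARTER = 480
DEFAULT_TEMPO_BPM = 120


def _vlq(value: int) -> bytes:
    """MIDI variable-length quantity encoding."""
    if value < 0:
        raise ValueError("delta time must be non-negative")
    out = [value & 0x7F]
    value >>= 7
    while value:
        out.append(0x80 | (value & 0x7F))
        value >>= 7
    return bytes(reversed(out))


def melody_midi_pitches(mel: Melody) -> list[int]:
    pitches = [round(69 + 12 * math.log2(n.frequency / 440.0)) for n in mel.notes]
    bad = [p for p in pitches if not 0 <= p <= 127]
    if bad:
        raise ValueError(f"note frequency maps outside MIDI pitch range 0-127: {bad[:3]}")
    return pitches


def write_midi(mel: Melody, path: str | Path, *, tempo_bpm: int = DEFAULT_TEMPO_BPM) -> None:
    """Write a melody as a single-track (format 0) standard MIDI file."""
    if len(mel.notes) == 0:
        raise ValueError("refusing to write an empty melody")
    pitches = melody_midi_pitches(mel)
    track = bytearray()
    tempo = round(60_000_000 / tempo_bpm)  # microseconds per quarter note
    track += _vlq(0) + bytes([0xFF, 0x51, 0x03]) + tempo.to_bytes(3, "big")
    for note, pitch in zip(mel.notes, pitches):
        ticks = int(note.duration * 4 * TICKS_PER_QUARTER)  # duration is a whole-note fraction
        track += _vlq(0) + bytes([0x90, pitch, note.velocity])
        track += _vlq(ticks) + bytes([0x80, pitch, 0])
    track += _vlq(0) + bytes([0xFF, 0x2F, 0x00])  # end of track
    header = (
        b"MThd" + (6).to_bytes(4, "big")
        + (0).to_bytes(2, "big") + (1).to_bytes(2, "big")
        + TICKS_PER_QUARTER.to_bytes(2, "big")
    )
    with Path(path).open("wb") as fh:
        fh.write(header)
        fh.write(b"MTrk" + len(track).to_bytes(4, "big") + bytes(track))
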