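"""Render paired tap timelines as Standard MIDI Files and stereo WAV audio.

The stereo image follows the two-virtual-player convention: the left
channel mixes player 1 and player 2 with a 4:1 amplitude ratio and the
right channel with the opposite ratio, so each player is lateralized but
both remain audible in both ears.  Player waveforms are built-in synthetic
percussive bursts with distinct spectra (so the two players do not fuse
into one source); timing, not timbre, is the controlled property.

MIDI encoding/decoding implements the small subset of Standard MIDI File
format 1 needed here (tempo meta-event, note on/off, variable-length delta
times), with a reader provided so written files can be verified by
round-trip.
"""

from __future__ import annotations

import math
import struct
from dataclasses import dataclass, field

import numpy as np
from scipy.io import wavfile

from .model import PairTimeline

BEAT_SECONDS = 0.5  # interbeat interval encoded by the tempo meta-event


class ClippingError(ValueError):
    """Mixed audio exceeded full scale after normalization."""


def synth_burst(
    sample_rate: int,
    tone_hz: float,
    duration: float = 0.08,
    decay: float = 0.015,
    noise_mix: float = 0.5,
    seed: int = 0,
) -> np.ndarray:
    """Synthetic snare-like percussive burst: decaying tone + noise, sharp attack."""
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    env = np.exp(-t / decay)
    tone = np.sin(2 * math.pi * tone_hz * t)
    noise = np.random.default_rng(seed).standard_normal(n)
    noise /= max(np.abs(noise).max(), 1e-12)
    w = env * ((1 - noise_mix) * tone + noise_mix * noise)
    w /= max(np.abs(w).max(), 1e-12)
    w[0] = 1.0  # hard attack: full amplitude at the onset sample
    return w


@dataclass(frozen=True)
class RenderSpec:
    """Rendering parameters for MIDI/WAV export."""

    sample_rate: int = 44100
    pan_ratio: float = 4.0
    gain: float = 0.9
    midi_notes: tuple[int, int] = (38, 38)  # GM acoustic snare
    velocity: int = 100
    ppq: int = 960
    note_ticks: int = 120  # note-off delay
    player_samples: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.sample_rate < 8000:
            raise ValueError("sample_rate must be >= 8000 Hz")
        if self.pan_ratio <= 0:
            raise ValueError("pan_ratio must be positive")
        if not 0 < self.gain <= 1:
            raise ValueError("gain must be in (0, 1]")

    def samples(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-player waveforms; defaults have distinct spectra per player."""
        if self.player_samples is not None:
            return self.player_samples
        return (
            synth_burst(self.sample_rate, tone_hz=185.0, seed=11),
            synth_burst(self.sample_rate, tone_hz=260.0, noise_mix=0.35, seed=23),
        )


# ---------------------------------------------------------------------------
# Standard MIDI File (format 1) writer / reader
# ---------------------------------------------------------------------------


def _varlen(value: int) -> bytes:
    if value < 0:
        raise ValueError("negative delta time")
    out = [value & 0x7F]
    value >>= 7
    while value:
        out.append(0x80 | (value & 0x7F))
        value >>= 7
    return bytes(reversed(out))


def _read_varlen(data: bytes, pos: int) -> tuple[int, int]:
    value = 0
    while True:
        b = data[pos]
        pos += 1
        value = (value << 7) | (b & 0x7F)
        if not b & 0x80:
            return value, pos


def _track_chunk(events: list[tuple[int, bytes]]) -> bytes:
    """Serialize (absolute_tick, event_bytes) pairs into an MTrk chunk."""
    events = sorted(events, key=lambda e: e[0])
    body = bytearray()
    prev = 0
    for tick, ev in events:
        body += _varlen(tick - prev) + ev
        prev = tick
    body += _varlen(0) + b"\xff\x2f\x00"  # end of track
    return b"MTrk" + struct.pack(">I", len(body)) + bytes(body)


def write_midi(timeline: PairTimeline, spec: RenderSpec, path) -> None:
    """Write a format-1 MIDI file: tempo track plus one track per player.

    Note-on ticks are ``round(t · PPQ / 0.5 s)``; the tempo meta-event sets
    500 ms per beat, so ticks map back to the original times exactly up to
    tick quantization (≈0.52 ms at PPQ 960).
    """
    tempo_us = int(round(BEAT_SECONDS * 1e6))
    tempo_track = _track_chunk([(0, b"\xff\x51\x03" + struct.pack(">I", tempo_us)[1:])])
    tracks = [tempo_track]
    for player in (1, 2):
        note = spec.midi_notes[player - 1]
        channel = player - 1
        events: list[tuple[int, bytes]] = []
        for t in timeline.taps(player):
            tick = int(round(t * spec.ppq / BEAT_SECONDS))
            events.append(
                (tick, bytes([0x90 | channel, note, spec.velocity]))
            )
            events.append((tick + spec.note_ticks, bytes([0x80 | channel, note, 0])))
        tracks.append(_track_chunk(events))
    header = b"MThd" + struct.pack(">IHHH", 6, 1, len(tracks), spec.ppq)
    with open(path, "wb") as fh:
        fh.write(header + b"".join(tracks))


def read_midi_onsets(path) -> tuple[list[np.ndarray], int, float]:
    """Parse a written MIDI file back into per-track note-on times.

    Returns ``(onsets, ppq, tempo_us)`` where ``onsets`` holds one array of
    note-on times (seconds) per non-empty track.  Supports the event subset
    emitted by :func:`write_midi` (running status included).
    """
    with open(path, "rb") as fh:
        data = fh.read()
    if data[:4] != b"MThd":
        raise ValueError("not a Standard MIDI File")
    _, fmt, ntrks, ppq = struct.unpack(">IHHH", data[4:14])
    pos = 14
    tempo_us = 500000.0
    onsets: list[np.ndarray] = []
    for _ in range(ntrks):
        if data[pos : pos + 4] != b"MTrk":
            raise ValueError("missing MTrk chunk")
        (length,) = struct.unpack(">I", data[pos + 4 : pos + 8])
        body = data[pos + 8 : pos + 8 + length]
        pos += 8 + length
        tick = 0
        p = 0
        status = 0
        track_onsets = []
        while p < len(body):
            delta, p = _read_varlen(body, p)
            tick += delta
            b0 = body[p]
            if b0 == 0xFF:
                meta_type = body[p + 1]
                mlen, q = _read_varlen(body, p + 2)
                payload = body[q : q + mlen]
                if meta_type == 0x51:
                    tempo_us = float(int.from_bytes(payload, "big"))
                p = q + mlen
                continue
            if b0 & 0x80:
                status = b0
                p += 1
            kind = status & 0xF0
            if kind in (0x80, 0x90, 0xA0, 0xB0, 0xE0):
                d1, d2 = body[p], body[p + 1]
                p += 2
                if kind == 0x90 and d2 > 0:
                    track_onsets.append(tick)
            elif kind in (0xC0, 0xD0):
                p += 1
            else:
                raise ValueError(f"unsupported status byte 0x{status:02x}")
        if track_onsets:
            seconds = np.asarray(track_onsets) * (tempo_us / 1e6) / ppq
            onsets.append(seconds)
    return onsets, ppq, tempo_us


# ---------------------------------------------------------------------------
# WAV rendering
# ---------------------------------------------------------------------------


def _player_tracks(
    timeline: PairTimeline, spec: RenderSpec, tail: float = 0.2
) -> tuple[np.ndarray, np.ndarray]:
    sr = spec.sample_rate
    s1, s2 = spec.samples()
    all_taps = np.concatenate([timeline.taps_p1, timeline.taps_p2])
    t_end = (all_taps.max() if all_taps.size else 0.0) + tail
    n = int(math.ceil(t_end * sr)) + max(len(s1), len(s2))
    tracks = []
    for taps, smp in ((timeline.taps_p1, s1), (timeline.taps_p2, s2)):
        tr = np.zeros(n)
        for t in taps:
            i = int(round(t * sr))  # onset at the nearest sample
            tr[i : i + len(smp)] += smp
        tracks.append(tr)
    return tracks[0], tracks[1]


def mix_stereo(
    p1: np.ndarray, p2: np.ndarray, spec: RenderSpec
) -> np.ndarray:
    """4:1 amplitude-panned stereo mix, shape (n, 2), peak ≤ gain by design."""
    r = spec.pan_ratio
    wl, wr = r / (r + 1.0), 1.0 / (r + 1.0)  # per-channel weights sum to 1
    left = wl * p1 + wr * p2
    right = wr * p1 + wl * p2
    audio = spec.gain * np.column_stack([left, right])
    peak = np.abs(audio).max() if audio.size else 0.0
    if peak > 1.0:
        raise ClippingError(f"peak {peak:.3f} exceeds full scale after mixing")
    return audio


def render_wav(timeline: PairTimeline, spec: RenderSpec, path) -> np.ndarray:
    """Render and write a 16-bit PCM stereo WAV; returns the float mix."""
    p1, p2 = _player_tracks(timeline, spec)
    audio = mix_stereo(p1, p2, spec)
    pcm = np.clip(np.round(audio * 32767.0), -32768, 32767).astype(np.int16)
    wavfile.write(path, spec.sample_rate, pcm)
    return audio


def detect_onsets(
    mono: np.ndarray,
    sample_rate: int,
    threshold: float = 0.1,
    refractory: float = 0.1,
) -> np.ndarray:
    """Sample indices where the signal first exceeds ``threshold`` after a gap.

    A simple attack detector adequate for the sharp-onset synthetic bursts;
    used as the read-back oracle for onset placement.
    """
    above = np.abs(mono) >= threshold
    gap = int(round(refractory * sample_rate))
    onsets = []
    i = 0
    n = len(above)
    while i < n:
        if above[i]:
            onsets.append(i)
            i += gap
        else:
            i += 1
    return np.asarray(onsets, dtype=int)
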