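"""Multimodal session container and its plain-text on-disk format.

A session directory holds one delimited text file per signal stream
(two-line header: stream name and sampling rate, then one sample per
line), a ``windows.tsv`` time map of baseline/encoding segments, and a
``truth.tsv`` with the latent engagement state of every encoding window.
Everything is float text, so a written session reads back bit-identical.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Stream",
    "Window",
    "SessionRecording",
    "CorruptSessionError",
    "write_session",
    "read_session",
]

#: streams every full session carries, with the config attribute naming its rate
EXPECTED_STREAMS = (
    "eeg_fz",
    "eeg_pz",
    "ecg",
    "eog",
    "pupil",
    "nirs_oxy_fp1",
    "nirs_deoxy_fp1",
    "nirs_tot_fp1",
    "nirs_oxy_fp2",
    "nirs_deoxy_fp2",
    "nirs_tot_fp2",
)


class CorruptSessionError(ValueError):
    """Raised when a session directory is missing files or internally inconsistent."""


@dataclass
class Stream:
    samples: np.ndarray
    fs: float

    def __eq__(self, other):
        if not isinstance(other, Stream):
            return NotImplemented
        return self.fs == other.fs and np.array_equal(
            self.samples, other.samples, equal_nan=True
        )


@dataclass(frozen=True)
class Window:
    start_s: float
    end_s: float
    kind: str  # "baseline" or "encoding"

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class SessionRecording:
    participant_id: str
    streams: dict[str, Stream]
    latent_states: np.ndarray  # per encoding window, "high"/"low"
    window_map: list[Window] = field(default_factory=list)

    @property
    def encoding_windows(self) -> list[Window]:
        return [w for w in self.window_map if w.kind == "encoding"]

    @property
    def baseline_window(self) -> Window:
        for w in self.window_map:
            if w.kind == "baseline":
                return w
        raise CorruptSessionError("session has no baseline segment")

    @property
    def duration_s(self) -> float:
        return max(w.end_s for w in self.window_map)

    def slice(self, stream: str, start_s: float, end_s: float) -> np.ndarray:
        """Samples of ``stream`` falling in [start_s, end_s)."""
        st = self.streams[stream]
        i0 = int(round(start_s * st.fs))
        i1 = int(round(end_s * st.fs))
        return st.samples[i0:i1]

    def validate(self) -> None:
        enc = self.encoding_windows
        if len(enc) == 0:
            raise CorruptSessionError("session has no encoding windows")
        if len(self.latent_states) != len(enc):
            raise CorruptSessionError(
                f"{len(self.latent_states)} latent states for {len(enc)} encoding windows"
            )
        dur = self.duration_s
        for name, st in self.streams.items():
            have = len(st.samples) / st.fs
            if have + 1e-9 < dur:
                raise CorruptSessionError(
                    f"stream {name!r} covers {have:.3f}s but windows extend to {dur:.3f}s"
                )

    def __eq__(self, other):
        if not isinstance(other, SessionRecording):
            return NotImplemented
        return (
            self.participant_id == other.participant_id
            and self.window_map == other.window_map
            and list(self.latent_states) == list(other.latent_states)
            and set(self.streams) == set(other.streams)
            and all(self.streams[k] == other.streams[k] for k in self.streams)
        )


def write_session(session: SessionRecording, directory: str | os.PathLike) -> list[str]:
    """Write one directory per session; returns the file paths written.

    Refuses to write a session with no encoding windows (nothing downstream
    could consume it).
    """
    session.validate()
    os.makedirs(directory, exist_ok=True)
    written = []
    for name, st in session.streams.items():
        path = os.path.join(directory, f"{name}.tsv")
        with open(path, "w") as fh:
            fh.write(f"stream\t{name}\n")
            fh.write(f"fs\t{st.fs!r}\n")
            np.savetxt(fh, st.samples, fmt="%.17g")
        written.append(path)
    wpath = os.path.join(directory, "windows.tsv")
    with open(wpath, "w") as fh:
        fh.write("start_s\tend_s\tkind\n")
        for w in session.window_map:
            fh.write(f"{w.start_s!r}\t{w.end_s!r}\t{w.kind}\n")
    written.append(wpath)
    tpath = os.path.join(directory, "truth.tsv")
    with open(tpath, "w") as fh:
        fh.write("participant_id\twindow_id\tlatent_state\n")
        for i, s in enumerate(session.latent_states):
            fh.write(f"{session.participant_id}\t{i}\t{s}\n")
    written.append(tpath)
    return written


def _read_stream(path: str) -> tuple[str, Stream]:
    with open(path) as fh:
        h1 = fh.readline().split("\t")
        h2 = fh.readline().split("\t")
        if len(h1) != 2 or h1[0] != "stream" or len(h2) != 2 or h2[0] != "fs":
            raise CorruptSessionError(f"{path}: malformed stream header")
        name = h1[1].strip()
        fs = float(h2[1])
        try:
            samples = np.loadtxt(fh, dtype=float)
        except ValueError as exc:  # pragma: no cover - loadtxt message varies
            raise CorruptSessionError(f"{path}: unreadable samples: {exc}") from exc
    return name, Stream(np.atleast_1d(samples), fs)


def read_session(directory: str | os.PathLike) -> SessionRecording:
    """Read a session directory written by :func:`write_session`.

    Raises :class:`CorruptSessionError` on missing files, header mismatch, or
    streams too short for the declared window map.
    """
    wpath = os.path.join(directory, "windows.tsv")
    tpath = os.path.join(directory, "truth.tsv")
    for p in (wpath, tpath):
        if not os.path.exists(p):
            raise CorruptSessionError(f"missing {os.path.basename(p)} in {directory}")
    window_map = []
    with open(wpath) as fh:
        fh.readline()
        for line in fh:
            start, end, kind = line.rstrip("\n").split("\t")
            window_map.append(Window(float(start), float(end), kind))
    states, pid = [], None
    with open(tpath) as fh:
        fh.readline()
        for line in fh:
            pid_i, _, state = line.rstrip("\n").split("\t")
            pid = pid_i
            states.append(state)
    if pid is None:
        raise CorruptSessionError(f"{tpath}: no encoding windows recorded")
    streams = {}
    for entry in sorted(os.listdir(directory)):
        if entry in ("windows.tsv", "truth.tsv") or not entry.endswith(".tsv"):
            continue
        name, stream = _read_stream(os.path.join(directory, entry))
        if name != entry[: -len(".tsv")]:
            raise CorruptSessionError(
                f"{entry}: header stream name {name!r} does not match filename"
            )
        streams[name] = stream
    session = SessionRecording(
        participant_id=pid,
        streams=streams,
        latent_states=np.array(states, dtype=object),
        window_map=window_map,
    )
    session.validate()
    return session
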