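"""Instrument-folder watching: decide when an output file is complete.

Potentiostat software often writes to the data file for the whole run,
so transferring a file the moment it appears would ship a truncated
experiment.  The watcher records (time, size) observations per matching
file and declares a file complete only when its size has been stable for
the full delay window (default 300 s) — i.e. it is no longer being
written to and has not grown within the delay time.  Complete files are
queued exactly once (deduplicated by path + content digest) for local
transfer into the pipeline inbox.

The clock is injectable so the delay logic is testable without waiting;
state serializes to JSON between scans.
"""

from __future__ import annotations

import hashlib
import json
import shutil
import time as _time
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

from .errors import WatchError

__all__ = [
    "WatchConfig",
    "WatchState",
    "QueuedItem",
    "file_is_complete",
    "scan_and_queue",
    "transfer",
]

MODES = ("file", "folder", "zipped-folder")


@dataclass
class WatchConfig:
    watch_dir: Path
    pattern: str = "*"
    delay: float = 300.0  # seconds of required size stability
    mode: str = "file"
    clock: object = _time.time  # injectable time source

    def __post_init__(self) -> None:
        self.watch_dir = Path(self.watch_dir)
        if self.delay <= 0:
            raise WatchError("delay must be > 0 seconds")
        if self.mode not in MODES:
            raise WatchError(f"mode must be one of {MODES}, got {self.mode!r}")


@dataclass
class QueuedItem:
    path: Path
    digest: str
    mode: str


@dataclass
class WatchState:
    """Per-path observation history plus the set of already-queued digests."""

    observations: dict[str, list[tuple[float, int]]] = field(default_factory=dict)
    queued: set[str] = field(default_factory=set)  # "path|sha256" keys

    def to_json(self) -> str:
        return json.dumps(
            {"observations": self.observations, "queued": sorted(self.queued)},
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "WatchState":
        doc = json.loads(text)
        return cls(
            observations={
                k: [(float(t), int(s)) for t, s in v]
                for k, v in doc.get("observations", {}).items()
            },
            queued=set(doc.get("queued", [])),
        )


def file_is_complete(
    observations: list[tuple[float, int]],
    delay: float,
    now: float,
) -> bool:
    """True iff the size has been stable for at least ``delay`` seconds.

    Concretely: every observation inside ``[now - delay, now]`` reports
    the latest size, and the size has held since at least ``delay``
    seconds ago (the first observation of the current size is that old).
    A single fresh observation is never complete — stability must be
    demonstrated over the whole window.
    """
    if not observations:
        raise WatchError("need at least one observation")
    obs = sorted(observations)
    latest_size = obs[-1][1]
    for t, size in obs:
        if t >= now - delay and size != latest_size:
            return False
    stable_since = obs[-1][0]
    for t, size in reversed(obs):
        if size != latest_size:
            break
        stable_since = t
    return now - stable_since >= delay


def _dir_size(path: Path) -> int:
    return sum(p.stat().st_size for p in path.rglob("*") if p.is_file())


def _digest_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _digest_dir(path: Path) -> str:
    h = hashlib.sha256()
    for p in sorted(path.rglob("*")):
        if p.is_file():
            h.update(str(p.relative_to(path)).encode())
            h.update(_digest_file(p).encode())
    return h.hexdigest()


def scan_and_queue(
    cfg: WatchConfig,
    state: WatchState | None = None,
) -> tuple[list[QueuedItem], WatchState]:
    """One watch pass: observe matching entries, queue the complete ones.

    Entries are files (``file`` mode) or directories (``folder`` /
    ``zipped-folder``); directory size is the recursive sum of its files.
    A complete entry is queued at most once per (path, content digest).
    """
    if state is None:
        state = WatchState()
    if not cfg.watch_dir.is_dir():
        raise WatchError(f"watch directory {cfg.watch_dir} is not readable")
    now = float(cfg.clock())
    if cfg.mode == "file":
        entries = [p for p in sorted(cfg.watch_dir.glob(cfg.pattern)) if p.is_file()]
    else:
        entries = [p for p in sorted(cfg.watch_dir.glob(cfg.pattern)) if p.is_dir()]

    queue: list[QueuedItem] = []
    for entry in entries:
        size = entry.stat().st_size if entry.is_file() else _dir_size(entry)
        key = str(entry)
        history = state.observations.setdefault(key, [])
        history.append((now, size))
        if not file_is_complete(history, cfg.delay, now):
            continue
        digest = _digest_file(entry) if entry.is_file() else _digest_dir(entry)
        dedup = f"{key}|{digest}"
        if dedup in state.queued:
            continue
        state.queued.add(dedup)
        queue.append(QueuedItem(entry, digest, cfg.mode))
    return queue, state


def transfer(items: list[QueuedItem], inbox: str | Path) -> list[Path]:
    """Copy queued items into the inbox (zipping directories when the
    watch mode asks for it); returns the created paths."""
    inbox = Path(inbox)
    inbox.mkdir(parents=True, exist_ok=True)
    out = []
    for item in items:
        if item.mode == "file":
            dest = inbox / item.path.name
            shutil.copy2(item.path, dest)
        elif item.mode == "folder":
            dest = inbox / item.path.name
            shutil.copytree(item.path, dest, dirs_exist_ok=True)
        else:  # zipped-folder
            dest = inbox / f"{item.path.name}.zip"
            with zipfile.ZipFile(dest, "w", zipfile.ZIP_DEFLATED) as zf:
                for p in sorted(item.path.rglob("*")):
                    if p.is_file():
                        zf.write(p, f"{item.path.name}/{p.relative_to(item.path)}")
        out.append(dest)
    return out
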