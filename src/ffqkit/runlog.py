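"""Timestamped run log.

Every processing run produces a log alongside each output file: NOTE entries
for general process information (default codes assigned, missing
frequencies) and ERROR entries (food codes with no nutrient data). The log
is machine-readable line by line with the fixed grammar::

    <ISO8601 UTC>\t<LEVEL>\t<participant id or '-'>\t<message>

so missing-frequency counts per participant can be recomputed from the log
alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

__all__ = ["LogEntry", "RunLog"]

LEVELS = ("NOTE", "ERROR")


@dataclass(frozen=True)
class LogEntry:
    timestamp: str  # ISO-8601 UTC
    level: str
    participant_id: str  # "-" for run-level entries
    message: str

    def render(self) -> str:
        return f"{self.timestamp}\t{self.level}\t{self.participant_id}\t{self.message}"


def _now() -> str:
    return datetime.now(timezone.utc).strftime("%Y-%m-%dT%H:%M:%S.%fZ")


@dataclass
class RunLog:
    entries: list[LogEntry] = field(default_factory=list)

    def add(self, level: str, participant_id: str, message: str) -> None:
        if level not in LEVELS:
            raise ValueError(f"unknown log level {level!r}")
        self.entries.append(LogEntry(_now(), level, participant_id or "-", message))

    def note(self, participant_id: str, message: str) -> None:
        self.add("NOTE", participant_id, message)

    def error(self, participant_id: str, message: str) -> None:
        self.add("ERROR", participant_id, message)

    def extend(self, other: "RunLog") -> None:
        self.entries.extend(other.entries)

    def count(self, level: str | None = None) -> int:
        if level is None:
            return len(self.entries)
        return sum(1 for e in self.entries if e.level == level)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(
            "".join(e.render() + "\n" for e in self.entries), encoding="utf-8"
        )

    @classmethod
    def read(cls, path: str | Path) -> "RunLog":
        log = cls()
        for lineno, line in enumerate(
            Path(path).read_text(encoding="utf-8").splitlines(), 1
        ):
            if not line:
                continue
            parts = line.split("\t", 3)
            if len(parts) != 4 or parts[1] not in LEVELS:
                raise ValueError(f"malformed log line {lineno}: {line!r}")
            log.entries.append(LogEntry(*parts))
        return log
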