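"""Centralized write-ahead logging and error routing.

Every command a module is about to execute is logged *before* execution,
so a crash mid-command still leaves the command on record.  Error reports
are routed through a configurable tolerance policy, which is what makes
unattended automation practical: a survey run can log-and-continue past
warnings that would stop an interactive session.
"""

from __future__ import annotations

import threading
from dataclasses import dataclass, field
from enum import Enum
from fractions import Fraction
from pathlib import Path
from typing import Callable, Iterable, Optional

from lxml import etree

from .hcoords import Timestamp128, now as _now

__all__ = [
    "LogRecord",
    "LogHandler",
    "ErrorReport",
    "ErrorPolicy",
    "Disposition",
    "ErrorHandler",
    "load_error_table",
    "write_error_table",
    "DEFAULT_ERROR_TABLE",
]


class ErrorPolicy(str, Enum):
    """Error tolerance levels for automated runs."""

    STRICT = "strict"  # any warning or error aborts
    TOLERANT = "tolerant"  # warnings continue, errors abort
    PERMISSIVE = "permissive"  # log everything, continue (fatal still aborts)


class Disposition(str, Enum):
    CONTINUE = "continue"
    ABORT = "abort"


KINDS = ("command", "info", "warning", "error")
SEVERITIES = ("warning", "error", "fatal")


@dataclass(frozen=True)
class LogRecord:
    ts: Timestamp128
    origin: str
    kind: str
    text: str
    seq: int

    def to_line(self) -> str:
        frac = Fraction(self.ts.fraction, 2**64)
        ts = f"{self.ts.seconds}+{float(frac):.9f}"
        text = self.text.replace("\t", " ").replace("\n", " ")
        return f"{self.seq}\t{ts}\t{self.origin}\t{self.kind}\t{text}"


@dataclass(frozen=True)
class ErrorReport:
    origin: str
    severity: str  # warning | error | fatal
    code: int
    message: str
    context: str = ""


class LogHandler:
    """Append-only event log with strictly increasing sequence numbers.

    Records are kept in memory and, if ``path`` is given, durably appended
    (one tab-separated UTF-8 line per record, flushed per write).
    """

    def __init__(self, path: Optional[Path] = None, clock: Callable[[], Timestamp128] = None):
        self._records: list[LogRecord] = []
        self._seq = 0
        self._lock = threading.Lock()
        self._path = Path(path) if path else None
        self._clock = clock or (lambda: _now())
        if self._path:
            self._path.parent.mkdir(parents=True, exist_ok=True)

    def log(self, origin: str, kind: str, text: str) -> int:
        """Append a record and return its sequence number.

        Callers log commands *before* executing them (write-ahead).
        """
        if kind not in KINDS:
            raise ValueError(f"unknown log kind {kind!r}")
        with self._lock:
            self._seq += 1
            rec = LogRecord(self._clock(), origin, kind, text, self._seq)
            self._records.append(rec)
            if self._path:
                with open(self._path, "a", encoding="utf-8") as fh:
                    fh.write(rec.to_line() + "\n")
                    fh.flush()
            return rec.seq

    @property
    def records(self) -> list[LogRecord]:
        return list(self._records)

    def query(
        self,
        origin: Optional[str] = None,
        kind: Optional[str] = None,
        t_min: Optional[Timestamp128] = None,
        t_max: Optional[Timestamp128] = None,
    ) -> list[LogRecord]:
        """Filtered view of the log, preserving sequence order."""
        out = []
        for r in self._records:
            if origin is not None and r.origin != origin:
                continue
            if kind is not None and r.kind != kind:
                continue
            if t_min is not None and r.ts < t_min:
                continue
            if t_max is not None and r.ts > t_max:
                continue
            out.append(r)
        return out


#: Minimal built-in error-code table; support folders may extend it.
DEFAULT_ERROR_TABLE: dict[int, tuple[str, str]] = {
    1: ("warning", "generic warning"),
    2: ("error", "generic error"),
    3: ("fatal", "fatal condition"),
    10: ("error", "raw data integrity failure"),
    11: ("error", "module command failed"),
    12: ("warning", "module command warning"),
}


def write_error_table(path: Path, table: dict[int, tuple[str, str]]) -> None:
    root = etree.Element("beb-errors")
    for code in sorted(table):
        severity, template = table[code]
        e = etree.SubElement(root, "error")
        e.set("code", str(code))
        e.set("severity", severity)
        e.text = template
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_bytes(etree.tostring(root, pretty_print=True, encoding="utf-8"))


def load_error_table(path: Path) -> dict[int, tuple[str, str]]:
    root = etree.parse(str(path)).getroot()
    table = {}
    for e in root.findall("error"):
        table[int(e.get("code"))] = (e.get("severity"), e.text or "")
    return table


class ErrorHandler:
    """Routes error reports through a tolerance policy and logs them all."""

    def __init__(
        self,
        log: LogHandler,
        table: Optional[dict[int, tuple[str, str]]] = None,
        reporter: Optional[Callable[[ErrorReport], None]] = None,
    ):
        self.log = log
        self.table = dict(table) if table is not None else dict(DEFAULT_ERROR_TABLE)
        # optional issue-tracker hook; default is a no-op
        self.reporter = reporter
        self.reports: list[ErrorReport] = []

    def classify(self, code: int) -> int:
        """Return the code if it is defined in the table, else 0 (unclassified)."""
        return code if code in self.table else 0

    def report(self, report: ErrorReport, policy: ErrorPolicy | str) -> Disposition:
        policy = ErrorPolicy(policy)
        if report.severity not in SEVERITIES:
            raise ValueError(f"unknown severity {report.severity!r}")
        report = ErrorReport(
            report.origin,
            report.severity,
            self.classify(report.code),
            report.message,
            report.context,
        )
        self.reports.append(report)
        kind = "warning" if report.severity == "warning" else "error"
        self.log.log(report.origin, kind, f"[{report.severity}:{report.code}] {report.message}")
        if self.reporter is not None:
            self.reporter(report)
        if report.severity == "fatal":
            return Disposition.ABORT
        if policy is ErrorPolicy.STRICT:
            return Disposition.ABORT
        if policy is ErrorPolicy.TOLERANT:
            return Disposition.ABORT if report.severity == "error" else Disposition.CONTINUE
        return Disposition.CONTINUE
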