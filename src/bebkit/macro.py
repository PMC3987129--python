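"""Macro interpreter coordinating named module endpoints.

Automated correlative experiments are driven by small text macros that
coordinate *modules* — named, FIFO-queued state machines contributed by
plug-ins (a pump, a stage, the data manager...).  The language is
line-oriented and deliberately small: variables with ``$var``
interpolation, arithmetic, IF/WHILE blocks, and the coordination
primitives SEND (enqueue and continue), CALL (enqueue and wait for the
reply), WAITIDLE, RESERVE/RELEASE of shared resources, SLEEP, PROMPT and
LOG.  Every command is logged *before* execution, and module errors are
routed through the configurable tolerance policy so unattended runs can
decide whether to push on.

Grammar (EBNF, case-insensitive keywords, ``#`` comments)::

    program    = { line } ;
    line       = set | if | else | endif | while | endwhile | send | call
               | waitidle | sleep | prompt | log | reserve | release ;
    set        = "SET" name "=" expr ;
    if         = "IF" expr ;            while    = "WHILE" expr ;
    send       = "SEND" module command { arg } ;
    call       = "CALL" module command { arg } ;
    waitidle   = "WAITIDLE" module ;    sleep    = "SLEEP" expr ;
    prompt     = "PROMPT" name text ;   log      = "LOG" text ;
    reserve    = "RESERVE" name ;       release  = "RELEASE" name ;
    expr       = sum [ cmp sum ] ;      cmp      = "="|"≠"|"!="|"<"|">"|"≤"|"<="|"≥"|">=" ;
    sum        = term { ("+"|"-") term } ;
    term       = atom { ("*"|"×"|"/"|"÷") atom } ;
    atom       = number | quoted text | "$" name | bareword ;
"""

from __future__ import annotations

import re
import socket
import socketserver
import threading
import time as _time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

from .errorlog import Disposition, ErrorHandler, ErrorPolicy, ErrorReport, LogHandler

__all__ = [
    "MacroSyntaxError",
    "MacroRuntimeError",
    "ModuleCommandError",
    "ModuleCommandWarning",
    "Instruction",
    "MacroProgram",
    "parse",
    "ModuleEndpoint",
    "Engine",
    "RunReport",
    "MockClock",
    "CronEntry",
    "CronTable",
    "parse_crontab",
    "ApplicationServer",
]


class MacroSyntaxError(ValueError):
    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


class MacroRuntimeError(RuntimeError):
    pass


class ModuleCommandError(RuntimeError):
    """Raised by module handlers to signal a command failure."""


class ModuleCommandWarning(RuntimeError):
    """Raised by module handlers to signal a non-fatal problem."""


# --- parsing ---------------------------------------------------------------

@dataclass(frozen=True)
class Instruction:
    kind: str
    args: tuple
    line: int
    target: int = -1  # jump target for IF/ELSE/WHILE/ENDWHILE

    def with_target(self, target: int) -> "Instruction":
        return Instruction(self.kind, self.args, self.line, target)


@dataclass
class MacroProgram:
    name: str
    instructions: list[Instruction]


_KEYWORDS = {
    "SET", "IF", "ELSE", "ENDIF", "WHILE", "ENDWHILE", "SEND", "CALL",
    "WAITIDLE", "SLEEP", "PROMPT", "LOG", "RESERVE", "RELEASE",
}

_NAME_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_-]*$")


def _split_words(text: str) -> list[str]:
    """Whitespace split honoring double-quoted strings."""
    return [w for w in re.findall(r'"[^"]*"|\S+', text)]


def parse(text: str, name: str = "macro") -> MacroProgram:
    """Compile macro text into an instruction list with resolved jumps."""
    raw_instructions: list[Instruction] = []
    stack: list[tuple[str, int, int]] = []  # (kind, instr index, source line)
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        words = _split_words(line)
        kw = words[0].upper()
        if kw not in _KEYWORDS:
            raise MacroSyntaxError(f"unknown keyword {words[0]!r}", lineno)
        idx = len(raw_instructions)
        if kw == "SET":
            if len(words) < 4 or words[2] != "=" or not _NAME_RE.match(words[1]):
                raise MacroSyntaxError("expected SET <name> = <expr>", lineno)
            raw_instructions.append(Instruction("SET", (words[1], words[3:]), lineno))
        elif kw in ("IF", "WHILE"):
            if len(words) < 2:
                raise MacroSyntaxError(f"{kw} needs a condition", lineno)
            raw_instructions.append(Instruction(kw, (words[1:],), lineno))
            stack.append((kw, idx, lineno))
        elif kw == "ELSE":
            if not stack or stack[-1][0] != "IF":
                raise MacroSyntaxError("ELSE without IF", lineno)
            kind, if_idx, if_line = stack.pop()
            raw_instructions.append(Instruction("ELSE", (), lineno))
            raw_instructions[if_idx] = raw_instructions[if_idx].with_target(idx + 1)
            stack.append(("ELSE", idx, if_line))
        elif kw == "ENDIF":
            if not stack or stack[-1][0] not in ("IF", "ELSE"):
                raise MacroSyntaxError("ENDIF without IF", lineno)
            kind, open_idx, _ = stack.pop()
            raw_instructions.append(Instruction("ENDIF", (), lineno))
            raw_instructions[open_idx] = raw_instructions[open_idx].with_target(idx)
        elif kw == "ENDWHILE":
            if not stack or stack[-1][0] != "WHILE":
                raise MacroSyntaxError("ENDWHILE without WHILE", lineno)
            _, while_idx, _ = stack.pop()
            raw_instructions.append(Instruction("ENDWHILE", (), lineno, target=while_idx))
            raw_instructions[while_idx] = raw_instructions[while_idx].with_target(idx + 1)
        elif kw in ("SEND", "CALL"):
            if len(words) < 3:
                raise MacroSyntaxError(f"{kw} needs <module> <command>", lineno)
            raw_instructions.append(Instruction(kw, (words[1], words[2], words[3:]), lineno))
        elif kw == "WAITIDLE":
            if len(words) != 2:
                raise MacroSyntaxError("WAITIDLE needs <module>", lineno)
            raw_instructions.append(Instruction(kw, (words[1],), lineno))
        elif kw == "SLEEP":
            if len(words) < 2:
                raise MacroSyntaxError("SLEEP needs a duration", lineno)
            raw_instructions.append(Instruction(kw, (words[1:],), lineno))
        elif kw == "PROMPT":
            if len(words) < 3 or not _NAME_RE.match(words[1]):
                raise MacroSyntaxError("expected PROMPT <name> <text>", lineno)
            raw_instructions.append(Instruction(kw, (words[1], " ".join(words[2:])), lineno))
        elif kw == "LOG":
            raw_instructions.append(Instruction(kw, (" ".join(words[1:]),), lineno))
        elif kw in ("RESERVE", "RELEASE"):
            if len(words) != 2:
                raise MacroSyntaxError(f"{kw} needs <resource>", lineno)
            raw_instructions.append(Instruction(kw, (words[1],), lineno))
    if stack:
        kind, _, open_line = stack[-1]
        block = "WHILE" if kind == "WHILE" else "IF"
        raise MacroSyntaxError(f"unbalanced {block} block", open_line)
    return MacroProgram(name, raw_instructions)


# --- expressions -----------------------------------------------------------

_NUM_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")
_CMP = {"=", "≠", "!=", "<", ">", "≤", "<=", "≥", ">="}
_ADD = {"+", "-", "−"}
_MUL = {"*", "×", "/", "÷"}


def _interp(word: str, variables: dict) -> object:
    """Resolve one token: quoted text, $var, number, or bare word."""
    if word.startswith('"') and word.endswith('"'):
        return re.sub(r"\$([A-Za-z_][A-Za-z0-9_-]*)", lambda m: str(variables.get(m.group(1), "")), word[1:-1])
    if word.startswith("$"):
        name = word[1:]
        if name not in variables:
            raise MacroRuntimeError(f"undefined variable {name!r}")
        return variables[name]
    if _NUM_RE.match(word):
        f = float(word)
        return int(f) if f.is_integer() else f
    return word


def _numeric(v) -> float:
    if isinstance(v, (int, float)):
        return v
    try:
        f = float(v)
        return int(f) if f.is_integer() else f
    except (TypeError, ValueError):
        raise MacroRuntimeError(f"not a number: {v!r}") from None


def eval_expr(words: Sequence[str], variables: dict) -> object:
    """Evaluate a token sequence: comparison over sums over products."""
    tokens = list(words)
    cmp_at = [i for i, t in enumerate(tokens) if t in _CMP]
    if len(cmp_at) > 1:
        raise MacroRuntimeError("chained comparisons are not supported")
    if cmp_at:
        i = cmp_at[0]
        lhs = eval_expr(tokens[:i], variables)
        rhs = eval_expr(tokens[i + 1:], variables)
        op = tokens[i]
        if isinstance(lhs, str) or isinstance(rhs, str):
            # compare as text unless both parse as numbers
            try:
                lhs, rhs = _numeric(lhs), _numeric(rhs)
            except MacroRuntimeError:
                lhs, rhs = str(lhs), str(rhs)
        if op == "=":
            return 1 if lhs == rhs else 0
        if op in ("≠", "!="):
            return 1 if lhs != rhs else 0
        if op == "<":
            return 1 if lhs < rhs else 0
        if op == ">":
            return 1 if lhs > rhs else 0
        if op in ("≤", "<="):
            return 1 if lhs <= rhs else 0
        return 1 if lhs >= rhs else 0
    if not tokens:
        raise MacroRuntimeError("empty expression")
    # products first, then sums, strictly left to right within a level
    values: list[object] = []
    ops: list[str] = []
    cur = _interp(tokens[0], variables)
    i = 1
    while i < len(tokens):
        op = tokens[i]
        if op in _MUL:
            rhs = _interp(tokens[i + 1], variables)
            a, b = _numeric(cur), _numeric(rhs)
            cur = a * b if op in ("*", "×") else a / b
            i += 2
        elif op in _ADD:
            values.append(cur)
            ops.append("+" if op == "+" else "-")
            cur = _interp(tokens[i + 1], variables)
            i += 2
        else:
            raise MacroRuntimeError(f"unexpected token {op!r} in expression")
    values.append(cur)
    if not ops:
        return values[0]
    acc = _numeric(values[0])
    for op, v in zip(ops, values[1:]):
        v = _numeric(v)
        acc = acc + v if op == "+" else acc - v
    return int(acc) if isinstance(acc, float) and acc.is_integer() else acc


def _truthy(v) -> bool:
    if isinstance(v, (int, float)):
        return v != 0
    return bool(v)


# --- modules ---------------------------------------------------------------

MINIMAL_COMMANDS = ("status", "noop", "abort")


class ModuleEndpoint:
    """A named FIFO-queued state machine addressable from macros."""

    def __init__(self, name: str, handler: Callable[[str, list], object]):
        self.name = name
        self.handler = handler
        self.queue: list[tuple[str, list, dict]] = []
        self.state = "idle"  # idle | busy | error
        self.executed: list[tuple[str, list]] = []  # observable command history

    def enqueue(self, command: str, args: list) -> dict:
        ticket = {"done": False, "result": None, "error": None}
        self.queue.append((command, args, ticket))
        return ticket

    def pump_one(self, log: LogHandler) -> Optional[dict]:
        """Execute the head of the queue; write-ahead log first."""
        if not self.queue:
            self.state = "idle"
            return None
        command, args, ticket = self.queue.pop(0)
        log.log(self.name, "command", f"{command} {' '.join(map(str, args))}".strip())
        self.state = "busy"
        try:
            if command == "abort":
                self.queue.clear()
            result = self.handler(command, list(args))
            ticket["result"] = "idle" if command == "status" else result
            self.executed.append((command, list(args)))
            self.state = "idle" if self.queue == [] else "busy"
        except BaseException as exc:
            self.executed.append((command, list(args)))
            self.state = "error"
            ticket["error"] = exc
        ticket["done"] = True
        return ticket


class MockClock:
    """Deterministic clock: SLEEP advances it instantly."""

    def __init__(self, start: float = 0.0):
        self.t = start

    def time(self) -> float:
        return self.t

    def sleep(self, seconds: float) -> None:
        self.t += seconds


@dataclass
class RunReport:
    status: str = "ok"  # ok | error | aborted
    variables: dict = field(default_factory=dict)
    events: list[str] = field(default_factory=list)
    error: Optional[str] = None


class Engine:
    """Executes macro programs against registered module endpoints."""

    def __init__(
        self,
        log: Optional[LogHandler] = None,
        error_handler: Optional[ErrorHandler] = None,
        clock=None,
        responder: Optional[Callable[[str], object]] = None,
        step_budget: int = 1_000_000,
        call_timeout: float = 60.0,
    ):
        self.log = log or LogHandler()
        self.errors = error_handler or ErrorHandler(self.log)
        self.clock = clock or MockClock()
        self.responder = responder
        self.step_budget = step_budget
        self.call_timeout = call_timeout
        self.modules: dict[str, ModuleEndpoint] = {}
        self._resources: dict[str, threading.Lock] = {}
        self._resources_guard = threading.Lock()
        self.macros: dict[str, MacroProgram] = {}

    # -- module registry ----------------------------------------------------

    def register_module(self, name: str, handler: Callable[[str, list], object]) -> ModuleEndpoint:
        """Register a module after probing the minimal command contract."""
        if name in self.modules:
            raise MacroRuntimeError(f"module {name!r} already registered")
        for cmd in MINIMAL_COMMANDS:
            try:
                handler(cmd, [])
            except BaseException:
                raise MacroRuntimeError(
                    f"module {name!r} does not handle required command {cmd!r}"
                ) from None
        ep = ModuleEndpoint(name, handler)
        self.modules[name] = ep
        return ep

    def unregister_module(self, name: str) -> None:
        self.modules.pop(name, None)

    def load_macros(self, macros_dir: Path) -> list[str]:
        """Parse every ``*.macro`` file in the support folder."""
        loaded = []
        for path in sorted(Path(macros_dir).glob("*.macro")):
            self.macros[path.stem] = parse(path.read_text(encoding="utf-8"), path.stem)
            loaded.append(path.stem)
        return loaded

    # -- helpers ------------------------------------------------------------

    def _endpoint(self, name: str) -> ModuleEndpoint:
        if name not in self.modules:
            raise MacroRuntimeError(f"unknown module {name!r}")
        return self.modules[name]

    def _pump_all(self) -> list[tuple[ModuleEndpoint, dict]]:
        done = []
        for ep in self.modules.values():
            while ep.queue:
                ticket = ep.pump_one(self.log)
                done.append((ep, ticket))
        return done

    def _resource(self, name: str) -> threading.Lock:
        with self._resources_guard:
            return self._resources.setdefault(name, threading.Lock())

    def _handle_ticket(self, ep: ModuleEndpoint, ticket: dict, policy: ErrorPolicy) -> Disposition:
        exc = ticket.get("error")
        if exc is None:
            return Disposition.CONTINUE
        severity = "warning" if isinstance(exc, ModuleCommandWarning) else "error"
        code = 12 if severity == "warning" else 11
        return self.errors.report(
            ErrorReport(ep.name, severity, code, str(exc)), policy
        )

    # -- execution ----------------------------------------------------------

    def run(
        self,
        program: MacroProgram | str,
        env: Optional[dict] = None,
        policy: ErrorPolicy | str = ErrorPolicy.TOLERANT,
        responder: Optional[Callable[[str], object]] = None,
    ) -> RunReport:
        """Interpret a program; the report carries final variables and log."""
        if isinstance(program, str):
            program = parse(program)
        policy = ErrorPolicy(policy)
        responder = responder or self.responder
        variables = dict(env or {})
        report = RunReport(variables=variables)
        held_resources: list[str] = []
        pc = 0
        steps = 0
        ins = program.instructions
        try:
            while pc < len(ins):
                steps += 1
                if steps > self.step_budget:
                    raise MacroRuntimeError(
                        f"step budget of {self.step_budget} exceeded (runaway loop?)"
                    )
                i = ins[pc]
                # write-ahead: the command is on record before any effect
                self.log.log(program.name, "command", f"{i.kind} @ line {i.line}")
                report.events.append(f"{i.kind}@{i.line}")
                if i.kind == "SET":
                    name, expr = i.args
                    variables[name] = eval_expr(expr, variables)
                elif i.kind in ("IF", "WHILE"):
                    if not _truthy(eval_expr(i.args[0], variables)):
                        pc = i.target
                        continue
                elif i.kind == "ELSE":
                    pc = i.target
                    continue
                elif i.kind == "ENDIF":
                    pass
                elif i.kind == "ENDWHILE":
                    pc = i.target
                    continue
                elif i.kind in ("SEND", "CALL"):
                    mod, command, argwords = i.args
                    ep = self._endpoint(mod)
                    args = [_interp(w, variables) for w in argwords]
                    ticket = ep.enqueue(command, args)
                    if i.kind == "CALL":
                        deadline = self.clock.time() + self.call_timeout
                        while not ticket["done"]:
                            ep.pump_one(self.log)
                            if self.clock.time() > deadline:
                                raise MacroRuntimeError(
                                    f"CALL {mod} {command} timed out"
                                )
                        disposition = self._handle_ticket(ep, ticket, policy)
                        if disposition is Disposition.ABORT:
                            report.status = "error"
                            report.error = str(ticket["error"])
                            return report
                        variables["_reply"] = ticket["result"]
                elif i.kind == "WAITIDLE":
                    ep = self._endpoint(i.args[0])
                    while ep.queue:
                        ticket = ep.pump_one(self.log)
                        disposition = self._handle_ticket(ep, ticket, policy)
                        if disposition is Disposition.ABORT:
                            report.status = "error"
                            report.error = str(ticket["error"])
                            return report
                elif i.kind == "SLEEP":
                    self.clock.sleep(_numeric(eval_expr(i.args[0], variables)))
                elif i.kind == "PROMPT":
                    name, text = i.args
                    if responder is None:
                        raise MacroRuntimeError(
                            f"PROMPT {name!r} with no responder in headless run"
                        )
                    variables[name] = responder(text)
                elif i.kind == "LOG":
                    msg = re.sub(
                        r"\$([A-Za-z_][A-Za-z0-9_-]*)",
                        lambda m: str(variables.get(m.group(1), "")),
                        i.args[0],
                    )
                    self.log.log(program.name, "info", msg)
                elif i.kind == "RESERVE":
                    lock = self._resource(i.args[0])
                    lock.acquire()
                    held_resources.append(i.args[0])
                elif i.kind == "RELEASE":
                    if i.args[0] in held_resources:
                        self._resource(i.args[0]).release()
                        held_resources.remove(i.args[0])
                pc += 1
                # cooperative pump: SEND-ed commands execute at instruction
                # boundaries, in strict per-module FIFO order
                for ep, ticket in self._pump_all():
                    disposition = self._handle_ticket(ep, ticket, policy)
                    if disposition is Disposition.ABORT:
                        report.status = "error"
                        report.error = str(ticket["error"])
                        return report
        except MacroRuntimeError as exc:
            report.status = "error"
            report.error = str(exc)
            self.errors.report(
                ErrorReport(program.name, "error", 11, str(exc)), ErrorPolicy.PERMISSIVE
            )
        finally:
            for r in held_resources:
                self._resource(r).release()
        return report


# --- cron ------------------------------------------------------------------

_WEEKDAYS = ("MON", "TUE", "WED", "THU", "FRI", "SAT", "SUN")


@dataclass
class CronEntry:
    hour: int
    minute: int
    weekdays: Optional[frozenset[int]] = None  # 0=Monday .. 6=Sunday
    macro_name: str = ""
    enabled: bool = True


def parse_crontab(text: str) -> list[CronEntry]:
    """Parse ``HH:MM [MON,TUE,...] macro-name`` lines; ``#`` comments."""
    entries = []
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        m = re.match(r"^(\d{1,2}):(\d{2})$", parts[0])
        if not m or len(parts) < 2:
            raise MacroSyntaxError("expected HH:MM [DAYS] macro-name", lineno)
        hour, minute = int(m.group(1)), int(m.group(2))
        if not (0 <= hour < 24 and 0 <= minute < 60):
            raise MacroSyntaxError("time out of range", lineno)
        weekdays = None
        rest = parts[1:]
        if len(rest) == 2:
            days = [d.strip().upper() for d in rest[0].split(",") if d.strip()]
            unknown = [d for d in days if d not in _WEEKDAYS]
            if unknown:
                raise MacroSyntaxError(f"unknown weekday {unknown[0]!r}", lineno)
            weekdays = frozenset(_WEEKDAYS.index(d) for d in days)
            rest = rest[1:]
        entries.append(CronEntry(hour, minute, weekdays, rest[0]))
    return entries


class CronTable:
    """Fires entries at most once per matching minute, in table order."""

    def __init__(self, entries: Sequence[CronEntry], engine: Optional[Engine] = None):
        self.entries = list(entries)
        self.engine = engine
        self._fired: set[tuple[int, tuple]] = set()

    def tick(self, when) -> list[str]:
        """``when``: datetime-like with year..minute and ``weekday()``.

        Returns the macro names launched this tick.  A missing macro is a
        logged error and does not block other entries.
        """
        minute_key = (when.year, when.month, when.day, when.hour, when.minute)
        launched = []
        for idx, e in enumerate(self.entries):
            if not e.enabled or e.hour != when.hour or e.minute != when.minute:
                continue
            if e.weekdays is not None and when.weekday() not in e.weekdays:
                continue
            key = (idx, minute_key)
            if key in self._fired:
                continue
            self._fired.add(key)
            if self.engine is not None:
                if e.macro_name in self.engine.macros:
                    self.engine.run(self.engine.macros[e.macro_name])
                else:
                    self.engine.log.log("cron", "error", f"missing macro {e.macro_name!r}")
                    continue
            launched.append(e.macro_name)
        return launched


# --- application server ----------------------------------------------------

class ApplicationServer:
    """Line-oriented TCP front end to one engine.

    Each newline-terminated UTF-8 line is a single macro instruction,
    ``RUN <macro-name>``, or ``GET <var>``; the reply is ``OK <payload>``
    or ``ERR <message>``.  Variables persist per connection.
    """

    def __init__(self, engine: Engine, host: str = "127.0.0.1", port: int = 0):
        outer = self

        class Handler(socketserver.StreamRequestHandler):
            def handle(self) -> None:
                variables: dict = {}
                while True:
                    raw = self.rfile.readline()
                    if not raw:
                        break
                    line = raw.decode("utf-8", "replace").strip()
                    if not line:
                        continue
                    try:
                        reply = outer._execute(line, variables)
                        self.wfile.write(f"OK {reply}\n".encode("utf-8"))
                    except Exception as exc:  # malformed input keeps the connection
                        self.wfile.write(f"ERR {exc}\n".encode("utf-8"))

        self._server = socketserver.ThreadingTCPServer((host, port), Handler)
        self._server.daemon_threads = True
        self.engine = engine
        self._thread: Optional[threading.Thread] = None

    @property
    def address(self) -> tuple[str, int]:
        return self._server.server_address

    def _execute(self, line: str, variables: dict) -> str:
        words = _split_words(line)
        kw = words[0].upper()
        if kw == "GET":
            if len(words) != 2 or words[1] not in variables:
                raise MacroRuntimeError(f"unknown variable {words[1] if len(words) > 1 else ''!r}")
            return str(variables[words[1]])
        if kw == "RUN":
            if len(words) != 2 or words[1] not in self.engine.macros:
                raise MacroRuntimeError(f"unknown macro {words[1] if len(words) > 1 else ''!r}")
            report = self.engine.run(self.engine.macros[words[1]], env=dict(variables))
            if report.status != "ok":
                raise MacroRuntimeError(report.error or report.status)
            variables.update(report.variables)
            return report.status
        program = parse(line, name="tcp")
        report = self.engine.run(program, env=dict(variables))
        if report.status != "ok":
            raise MacroRuntimeError(report.error or report.status)
        variables.clear()
        variables.update(report.variables)
        return ""

    def start(self) -> "ApplicationServer":
        self._thread = threading.Thread(target=self._server.serve_forever, daemon=True)
        self._thread.start()
        return self

    def stop(self) -> None:
        self._server.shutdown()
        self._server.server_close()
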