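"""Macro parsing, module FIFO semantics, policies, cron, TCP server."""

import socket
import threading
from datetime import datetime

import pytest
from hypothesis import given, settings, strategies as st

from bebkit.errorlog import ErrorPolicy
from bebkit.macro import (
    ApplicationServer,
    CronTable,
    Engine,
    MacroRuntimeError,
    MacroSyntaxError,
    ModuleCommandError,
    ModuleCommandWarning,
    parse,
    parse_crontab,
)

settings.register_profile("ci", derandomize=True, max_examples=30)
settings.load_profile("ci")


def ok_handler(recorder=None):
    def handler(command, args):
        if recorder is not None and command not in ("status", "noop", "abort"):
            recorder.append((command, list(args)))
        return None
    return handler


class TestParse:
    def test_counts_and_balance(self):
        p = parse("SET n = 0\nWHILE $n < 3\nSET n = $n + 1\nENDWHILE\nLOG done")
        assert len(p.instructions) == 5

    def test_missing_endif_names_the_if_line(self):
        with pytest.raises(MacroSyntaxError, match="line 2"):
            parse("LOG start\nIF 1\nLOG inside")

    def test_empty_program_is_runnable(self):
        assert Engine().run(parse("")).status == "ok"

    def test_unknown_keyword_rejected(self):
        with pytest.raises(MacroSyntaxError, match="FROB"):
            parse("FROB x")

    def test_comments_and_blank_lines_ignored(self):
        p = parse("# a comment\n\nSET x = 1  # trailing\n")
        assert len(p.instructions) == 1


class TestRun:
    def test_while_loop_reaches_predicted_state(self):
        rep = Engine().run("SET n = 0\nWHILE $n < 3\nSET n = $n + 1\nENDWHILE")
        assert rep.status == "ok" and rep.variables["n"] == 3

    def test_if_else_branches(self):
        rep = Engine().run(
            "SET x = 5\nIF $x > 3\nSET r = big\nELSE\nSET r = small\nENDIF"
        )
        assert rep.variables["r"] == "big"
        rep = Engine().run(
            "SET x = 1\nIF $x > 3\nSET r = big\nELSE\nSET r = small\nENDIF"
        )
        assert rep.variables["r"] == "small"

    def test_arithmetic_and_text(self):
        rep = Engine().run('SET a = 2 * 3 + 4\nSET b = "n=$a"')
        assert rep.variables["a"] == 10 and rep.variables["b"] == "n=10"

    def test_send_order_observed_fifo(self):
        log = []
        eng = Engine()
        eng.register_module("m", ok_handler(log))
        eng.run("SEND m a\nSEND m b\nSEND m c")
        assert [c for c, _ in log] == ["a", "b", "c"]

    def test_call_blocks_and_stores_reply(self):
        eng = Engine()
        eng.register_module("m", lambda c, a: 41 + 1 if c == "answer" else None)
        rep = eng.run("CALL m answer\nSET got = $_reply")
        assert rep.variables["got"] == 42

    def test_strict_policy_aborts_on_error(self):
        def bad(command, args):
            if command == "explode":
                raise ModuleCommandError("boom")
        eng = Engine()
        eng.register_module("m", bad)
        rep = eng.run("CALL m explode\nSET after = 1", policy="strict")
        assert rep.status == "error" and "after" not in rep.variables

    def test_permissive_policy_continues(self):
        def bad(command, args):
            if command == "explode":
                raise ModuleCommandError("boom")
        eng = Engine()
        eng.register_module("m", bad)
        rep = eng.run("SEND m explode\nSET after = 1", policy="permissive")
        assert rep.status == "ok" and rep.variables["after"] == 1

    def test_tolerant_policy_warnings_continue_errors_abort(self):
        def moody(command, args):
            if command == "warn":
                raise ModuleCommandWarning("meh")
            if command == "fail":
                raise ModuleCommandError("bad")
        eng = Engine()
        eng.register_module("m", moody)
        rep = eng.run("SEND m warn\nSET a = 1\nSEND m fail\nSET b = 1", policy="tolerant")
        assert rep.status == "error"
        assert rep.variables.get("a") == 1 and "b" not in rep.variables

    def test_step_budget_stops_runaway_loop(self):
        eng = Engine(step_budget=500)
        rep = eng.run("WHILE 1\nSET x = 1\nENDWHILE")
        assert rep.status == "error" and "budget" in rep.error

    def test_prompt_uses_responder(self):
        eng = Engine(responder=lambda text: "blue")
        rep = eng.run("PROMPT color favourite colour?")
        assert rep.variables["color"] == "blue"

    def test_prompt_without_responder_fails_fast(self):
        rep = Engine().run("PROMPT x gimme")
        assert rep.status == "error"

    def test_sleep_advances_mock_clock_instantly(self):
        eng = Engine()
        eng.run("SLEEP 3600")
        assert eng.clock.time() == 3600

    def test_unknown_module_is_an_error(self):
        rep = Engine().run("SEND ghost anything")
        assert rep.status == "error"

    @given(st.data())
    def test_fifo_per_module_random_schedules(self, data):
        """5 modules, interleaved sends; each module sees its own order."""
        names = ["m0", "m1", "m2", "m3", "m4"]
        schedule = data.draw(
            st.lists(st.sampled_from(names), min_size=1, max_size=100)
        )
        eng = Engine()
        logs = {n: [] for n in names}
        for n in names:
            eng.register_module(n, ok_handler(logs[n]))
        lines, sent = [], {n: [] for n in names}
        for i, n in enumerate(schedule):
            lines.append(f"SEND {n} cmd{i}")
            sent[n].append(f"cmd{i}")
        rep = eng.run("\n".join(lines))
        assert rep.status == "ok"
        for n in names:
            assert [c for c, _ in logs[n]] == sent[n]


class TestRegistration:
    def test_register_and_send(self):
        eng = Engine()
        eng.register_module("pump", ok_handler())
        assert eng.run("SEND pump start").status == "ok"

    def test_duplicate_name_rejected(self):
        eng = Engine()
        eng.register_module("pump", ok_handler())
        with pytest.raises(MacroRuntimeError):
            eng.register_module("pump", ok_handler())

    def test_handler_missing_minimal_command_refused(self):
        def partial(command, args):
            if command == "abort":
                raise NotImplementedError
        eng = Engine()
        with pytest.raises(MacroRuntimeError, match="abort"):
            eng.register_module("broken", partial)


class TestReserve:
    def test_critical_sections_never_overlap(self):
        """Concurrent macros RESERVE-ing one resource serialize their bodies."""
        eng = Engine()
        events = []
        guard = threading.Lock()

        def recorder(command, args):
            if command in ("enter", "exit"):
                with guard:
                    events.append((args[0], command))

        eng.register_module("m", recorder)
        macro = parse("RESERVE data-manager\nCALL m enter $tag\nCALL m exit $tag\nRELEASE data-manager")

        def worker(tag):
            assert eng.run(macro, env={"tag": tag}).status == "ok"

        threads = [threading.Thread(target=worker, args=(i,)) for i in range(8)]
        for t in threads:
            t.start()
        for t in threads:
            t.join()
        # oracle: interval overlap — each enter is followed by its own exit
        assert len(events) == 16
        for i in range(0, 16, 2):
            assert events[i][0] == events[i + 1][0]
            assert (events[i][1], events[i + 1][1]) == ("enter", "exit")

    def test_reserve_release_in_macro(self):
        eng = Engine()
        rep = eng.run("RESERVE r\nSET x = 1\nRELEASE r")
        assert rep.status == "ok"
        assert not eng._resource("r").locked()

    def test_lock_released_even_on_error(self):
        eng = Engine()
        rep = eng.run("RESERVE r\nSEND ghost x")
        assert rep.status == "error"
        assert not eng._resource("r").locked()

    def test_two_macros_serialize_on_shared_resource(self):
        eng = Engine()
        order = []

        def run_macro(tag):
            eng._resource("res").acquire()
            order.append((tag, "in"))
            order.append((tag, "out"))
            eng._resource("res").release()

        ts = [threading.Thread(target=run_macro, args=(i,)) for i in range(4)]
        for t in ts:
            t.start()
        for t in ts:
            t.join()
        # oracle: interval overlap check — every "in" is immediately
        # followed by the same macro's "out"
        for i in range(0, len(order), 2):
            assert order[i][0] == order[i + 1][0]
            assert order[i][1] == "in" and order[i + 1][1] == "out"


class TestCron:
    def table(self, engine=None):
        entries = parse_crontab("07:30 morning\n07:30 second\n08:00 MON,TUE weekly")
        return CronTable(entries, engine)

    def test_fires_once_per_matching_minute(self):
        t = self.table()
        when = datetime(2014, 3, 26, 7, 30)
        assert t.tick(when) == ["morning", "second"]  # table order
        assert t.tick(when) == []  # same minute: no refire
        assert t.tick(datetime(2014, 3, 27, 7, 30)) == ["morning", "second"]

    def test_non_matching_minute_fires_nothing(self):
        assert self.table().tick(datetime(2014, 3, 26, 7, 31)) == []

    def test_weekday_filter(self):
        t = self.table()
        monday = datetime(2014, 3, 24, 8, 0)
        wednesday = datetime(2014, 3, 26, 8, 0)
        assert t.tick(monday) == ["weekly"]
        assert t.tick(wednesday) == []

    def test_disabled_entries_never_fire(self):
        t = self.table()
        t.entries[0].enabled = False
        assert t.tick(datetime(2014, 3, 26, 7, 30)) == ["second"]

    def test_missing_macro_logged_not_fatal(self):
        eng = Engine()
        eng.macros["second"] = parse("SET x = 1", "second")
        t = self.table(eng)
        fired = t.tick(datetime(2014, 3, 26, 7, 30))
        assert fired == ["second"]
        assert any("missing macro" in r.text for r in eng.log.records)

    def test_bad_crontab_line_rejected(self):
        with pytest.raises(MacroSyntaxError):
            parse_crontab("25:99 broken")


class TestServer:
    @pytest.fixture
    def server(self):
        eng = Engine()
        eng.macros["hello"] = parse("SET greeting = hi", "hello")
        srv = ApplicationServer(eng).start()
        yield srv
        srv.stop()

    def talk(self, server, lines):
        with socket.create_connection(server.address, timeout=5) as s:
            f = s.makefile("rw", encoding="utf-8", newline="\n")
            replies = []
            for line in lines:
                f.write(line + "\n")
                f.flush()
                replies.append(f.readline().strip())
            return replies

    def test_set_then_get(self, server):
        assert self.talk(server, ["SET x = 5", "GET x"]) == ["OK", "OK 5"]

    def test_run_known_and_missing_macro(self, server):
        replies = self.talk(server, ["RUN hello", "GET greeting", "RUN missing"])
        assert replies[0] == "OK ok"
        assert replies[1] == "OK hi"
        assert replies[2].startswith("ERR")

    def test_malformed_line_keeps_connection_open(self, server):
        replies = self.talk(server, ["FROB x", "SET y = 1", "GET y"])
        assert replies[0].startswith("ERR")
        assert replies[1:] == ["OK", "OK 1"]

    def test_hundred_commands_preserve_order(self, server):
        lines = [f"SET v{i} = {i}" for i in range(100)] + [f"GET v{i}" for i in range(100)]
        replies = self.talk(server, lines)
        assert replies[:100] == ["OK"] * 100
        assert replies[100:] == [f"OK {i}" for i in range(100)]
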