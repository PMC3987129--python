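"""Coordinate instrument modules from a text macro.

Run:  python examples/03_macro_automation.py
"""

from bebkit.macro import Engine

engine = Engine()

def pump(command, args):
    if command == "dispense":
        print(f"  [pump] dispensing {args[0]} uL")
    return "ok"

def stage(command, args):
    if command == "move":
        print(f"  [stage] moving to x={args[0]}")
    return "ok"

engine.register_module("pump", pump)
engine.register_module("stage", stage)

report = engine.run("""
# visit three positions, dispense at each
SET x = 0
WHILE $x < 3
    SEND stage move $x
    CALL pump dispense 10
    SET x = $x + 1
ENDWHILE
LOG finished at x=$x
""", policy="tolerant")

print("status:", report.status, "| final x =", report.variables["x"])
print("log lines (written BEFORE each command executes):")
for rec in engine.log.records[-3:]:
    print("  ", rec.seq, rec.origin, rec.kind, rec.text)

# Each module is a FIFO queue: commands arrive and execute strictly in send
# order; CALL blocks for the reply, SEND continues immediately.
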