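"""Plug-in discovery, compatibility checking and activation ordering.

Plug-ins are described by a ``plugin.ini`` in their own folder under
``support/plugins/``.  Eight types exist; two of them have a fixed place
in the loading order: *viewportType* plug-ins (data-type definitions)
load first, *library* plug-ins immediately after, everything else behind
them.  Within those precedence bands the order is a stable topological
sort of the ``depends`` graph, ties broken lexicographically so plans are
reproducible.  Problems never abort activation: incompatible, malformed,
disabled or cyclically dependent plug-ins are skipped with a reason, and
skipping is closed under dependency.
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

from lxml import etree

from .vocab import CORE_VERSION, _version_key

__all__ = [
    "PLUGIN_TYPES",
    "PluginDescriptor",
    "ActivationPlan",
    "PluginError",
    "discover",
    "activation_order",
    "PluginRegistry",
]

PLUGIN_TYPES = (
    "viewportType",
    "library",
    "viewport",
    "collection",
    "importer",
    "tool",
    "database",
    "module",
)

#: Loading-order bands: data-type definitions, then libraries, then the rest.
_PRECEDENCE = {"viewportType": 0, "library": 1}
_DEFAULT_PRECEDENCE = 2


class PluginError(Exception):
    pass


@dataclass(frozen=True)
class PluginDescriptor:
    name: str
    ptype: str
    version: str = "0.0.0"
    core_min: str = "0.0.0"
    depends_on: tuple[str, ...] = ()
    provides_modules: tuple[str, ...] = ()
    description: str = ""
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.ptype not in PLUGIN_TYPES:
            raise PluginError(f"{self.name}: unknown plug-in type {self.ptype!r}")
        if self.ptype == "viewport" and len(self.depends_on) != 1:
            raise PluginError(
                f"{self.name}: a viewport must depend on exactly one viewportType"
            )

    @property
    def precedence(self) -> int:
        return _PRECEDENCE.get(self.ptype, _DEFAULT_PRECEDENCE)


@dataclass
class ActivationPlan:
    order: list[str] = field(default_factory=list)
    skipped: list[tuple[str, str]] = field(default_factory=list)  # (name, reason)


def _parse_ini(path: Path) -> PluginDescriptor:
    cp = configparser.ConfigParser()
    with open(path, encoding="utf-8") as fh:
        cp.read_file(fh)
    sec = cp["plugin"]
    if "type" not in sec or "name" not in sec:
        raise PluginError(f"{path}: missing required key")
    split = lambda s: tuple(x.strip() for x in s.split(",") if x.strip())
    return PluginDescriptor(
        name=sec["name"],
        ptype=sec["type"],
        version=sec.get("version", "0.0.0"),
        core_min=sec.get("core_min", "0.0.0"),
        depends_on=split(sec.get("depends", "")),
        provides_modules=split(sec.get("modules", "")),
        description=sec.get("description", ""),
    )


def discover(
    plugins_dir: Path, core_version: str = CORE_VERSION
) -> tuple[list[PluginDescriptor], list[tuple[str, str]]]:
    """Scan ``support/plugins/`` for descriptors.

    Returns (descriptors, skipped); a folder whose plugin.ini is missing,
    malformed, or requires a newer core lands in skipped with a reason.
    """
    plugins_dir = Path(plugins_dir)
    if not plugins_dir.is_dir():
        raise PluginError(f"plug-in folder {plugins_dir} does not exist")
    found: list[PluginDescriptor] = []
    skipped: list[tuple[str, str]] = []
    for sub in sorted(p for p in plugins_dir.iterdir() if p.is_dir()):
        ini = sub / "plugin.ini"
        if not ini.is_file():
            skipped.append((sub.name, "malformed: no plugin.ini"))
            continue
        try:
            desc = _parse_ini(ini)
        except (PluginError, configparser.Error, KeyError) as exc:
            skipped.append((sub.name, f"malformed: {exc}"))
            continue
        if _version_key(desc.core_min) > _version_key(core_version):
            skipped.append((desc.name, "incompatible: requires newer core"))
            continue
        found.append(desc)
    return found, skipped


def activation_order(
    descriptors: Iterable[PluginDescriptor],
    pre_skipped: Iterable[tuple[str, str]] = (),
) -> ActivationPlan:
    """Compute the dependency- and type-ordered activation sequence.

    Kahn's algorithm over the dependency graph, with the ready set kept
    as a priority queue on (precedence band, name) — so every plan is a
    valid topological order in which all viewportTypes precede all
    libraries precede the rest, and equal-priority ties are name-sorted.
    Disabled plug-ins, missing/disabled dependencies and cycle members
    are skipped; skipping propagates to dependents.
    """
    import heapq

    plan = ActivationPlan(skipped=list(pre_skipped))
    byname = {d.name: d for d in descriptors}
    skipped: dict[str, str] = {}
    for d in byname.values():
        if not d.enabled:
            skipped[d.name] = "disabled"
    # propagate missing/disabled dependencies transitively
    changed = True
    while changed:
        changed = False
        for d in byname.values():
            if d.name in skipped:
                continue
            for dep in d.depends_on:
                if dep not in byname:
                    skipped[d.name] = f"missing dependency {dep!r}"
                    changed = True
                    break
                if dep in skipped:
                    reason = "dependency disabled" if skipped[dep] == "disabled" else f"dependency {dep!r} skipped"
                    skipped[d.name] = reason
                    changed = True
                    break
    active = {n: d for n, d in byname.items() if n not in skipped}
    indeg = {n: 0 for n in active}
    dependents: dict[str, list[str]] = {n: [] for n in active}
    for d in active.values():
        for dep in d.depends_on:
            indeg[d.name] += 1
            dependents[dep].append(d.name)
    ready = [(active[n].precedence, n) for n, k in indeg.items() if k == 0]
    heapq.heapify(ready)
    order: list[str] = []
    while ready:
        _, name = heapq.heappop(ready)
        order.append(name)
        for dep_name in dependents[name]:
            indeg[dep_name] -= 1
            if indeg[dep_name] == 0:
                heapq.heappush(ready, (active[dep_name].precedence, dep_name))
    for name in active:
        if name not in order:
            skipped[name] = "dependency cycle"
    plan.order = order
    plan.skipped.extend(sorted(skipped.items()))
    return plan


class PluginRegistry:
    """Persistent enable/disable flags plus plan computation.

    Toggling a flag only takes effect at the next activation — plans are
    recomputed from scratch, mirroring a restart-based plug-in manager.
    """

    def __init__(self, plugins_dir: Path, core_version: str = CORE_VERSION):
        self.plugins_dir = Path(plugins_dir)
        self.core_version = core_version
        self._disabled: set[str] = set()
        self._load_flags()

    @property
    def _flags_path(self) -> Path:
        return self.plugins_dir / "enabled.xml"

    def _load_flags(self) -> None:
        if self._flags_path.exists():
            root = etree.parse(str(self._flags_path)).getroot()
            self._disabled = {e.get("name") for e in root.findall("plugin") if e.get("enabled") == "false"}

    def _save_flags(self) -> None:
        root = etree.Element("beb-plugin-registry")
        for name in sorted(self._disabled):
            e = etree.SubElement(root, "plugin")
            e.set("name", name)
            e.set("enabled", "false")
        self._flags_path.parent.mkdir(parents=True, exist_ok=True)
        self._flags_path.write_bytes(etree.tostring(root, pretty_print=True, encoding="utf-8"))

    def set_enabled(self, name: str, flag: bool) -> None:
        descriptors, _ = discover(self.plugins_dir, self.core_version)
        known = {d.name for d in descriptors}
        if name not in known and name not in self._disabled:
            raise PluginError(f"unknown plug-in {name!r}")
        if flag:
            self._disabled.discard(name)
        else:
            self._disabled.add(name)
        self._save_flags()

    def plan(self) -> ActivationPlan:
        descriptors, pre_skipped = discover(self.plugins_dir, self.core_version)
        descriptors = [
            replace(d, enabled=d.name not in self._disabled) for d in descriptors
        ]
        return activation_order(descriptors, pre_skipped)

    def active_modules(self) -> list[tuple[str, str]]:
        """(module name, providing plug-in) for every plug-in in the plan."""
        descriptors, _ = discover(self.plugins_dir, self.core_version)
        byname = {d.name: d for d in descriptors}
        plan = self.plan()
        out = []
        for name in plan.order:
            for mod in byname[name].provides_modules:
                out.append((mod, name))
        return out
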