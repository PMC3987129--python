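# bebkit

A headless Python core for managing **correlative biological experiment
data** — the situation where one subject (say, a single cell in a culture
dish) is measured by several instruments at several scales, and the
results must stay correlated in space and time: time-lapse light
microscopy of the dish, lysis of one selected cell, electron microscopy
of its lysate.

bebkit provides, as a library plus a thin `bebkit` command:

- **A local container format.** An experiment lives in a *bundle*
  (`<name>.bundle/`), a tree of *collections*, each with exactly four
  subfolders: `RawData/` (imported instrument files, never modified; MD5
  checksummed at import; optionally ZIP-compressed losslessly),
  `Annotations/` (XML metadata, thumbnails, previews, annotated views),
  `Cache/` (derived files, recomputable at any time) and `Collections/`
  (sub-collections). Everything is plain files, readable by any tool.
- **A hierarchical coordinate (HC) system.** Each collection or dataset
  stores its position *relative to its parent* as signed 64-bit integers
  in picometers, with standard errors. Frames compose by exact integer
  addition; errors combine in quadrature: for a path root → e₁ → … → eₙ,

  x_abs = Σᵢ xᵢ,  dx_abs = √(Σᵢ dxᵢ²).

  Time is absolute per entity: a 128-bit fixed-point timestamp — a signed
  64-bit count of seconds since 1904-01-01 00:00 UT (leap seconds
  ignored) plus an unsigned 64-bit fraction in units of 2⁻⁶⁴ s — so
  instruments calibrated against one clock produce directly comparable,
  drift-free stamps. A `scale` field controls display only: stored pm
  divided by scale (1000 → nm, 10⁶ → µm).
- **Controlled-vocabulary protocols.** Annotation templates assembled
  from a shared library of uniquely identified entries; editing a library
  entry propagates to every template that hasn't locally overridden it.
- **A macro engine.** Line-oriented macros (variables, IF/WHILE, `$var`
  interpolation) coordinate named *modules* — FIFO-queued state machines
  contributed by plug-ins — with SEND/CALL/WAITIDLE/RESERVE primitives, a
  cron-style scheduler, and an optional line-protocol TCP server. Every
  command is logged *before* it executes.
- **A typed plug-in registry** with dependency-ordered activation
  (data-type definitions load first, libraries second, the rest after,
  topologically sorted, reproducible tie-breaking).
- **Database synchronization.** A bundle pushes to an experiment/sample
  store (one experiment per bundle, one sample per collection); uploads
  are MD5-differential, cache files are never uploaded, and collections
  can be deleted locally and restored byte-identically from the server.

## Worked example

```sh
$ bebkit demo --seed 42 --out /tmp --name demo
/tmp/demo.bundle
$ bebkit verify /tmp/demo.bundle
local: checked 8, passed 8, failures 0
$ bebkit resolve-coords /tmp/demo.bundle/Collections/CellCulture/Collections/SingleCellLysis
x=4777016 pm  y=4157893 pm  z=0 pm
display (scale 1): 4.77702e+06, 4.15789e+06, 0
```

The demo bundle is the full correlative workflow in miniature: a
`CellCulture` collection whose coordinate record is the frame root and
which holds a simulated LM time-lapse stack (timestamps exactly one
frame interval apart in fixed-point arithmetic) and a fluorescence
trace; a `SingleCellLysis` sub-collection positioned at the selected
cell (pm relative to the dish); and an `EM` sub-sub-collection of
synthetic micrographs at sub-offsets. `verify` re-hashes every raw file
against the MD5 recorded at import; `resolve-coords` sums the relative
offsets down the tree into the root frame.

The `examples/` directory holds one short script per capability
(container + integrity, coordinates + time, macro automation, sync +
restore, image views); each prints the numbers it computes and a line on
what they mean.

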