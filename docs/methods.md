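# Methods

This note documents the models, conventions and numerical choices behind
bebkit, what its synthetic demo data does and does not emulate, and the
design decisions taken where the problem left the design open.

## The container model

A bundle is the root of a collection tree bound to a file-system path
(`<name>.bundle`). Every collection — the bundle included — owns exactly
four subfolders: `RawData`, `Annotations`, `Cache`, `Collections`. The
contract that makes the format trustworthy is the split of authority
between them:

- **RawData is immutable.** Files are copied in once; an MD5 of the
  uncompressed content is recorded in the dataset's metadata document at
  import, and `verify_integrity` re-hashes everything (transparently
  decompressing) against those records. Compression is per file, a
  single-entry deflate ZIP named `<original>.zip`; because the checksum
  covers the uncompressed bytes, compressing never changes identity.
- **Annotations holds all interpretation**: one canonical-XML document
  per collection (`collection.xml`) and per dataset (`<id>.xml`), plus
  thumbnail (≤128 px) and preview (≤512 px) PNGs and graphically
  annotated view images.
- **Cache is disposable.** Everything in it is a pure function of
  RawData + Annotations; `rebuild_cache` deletes and regenerates it, and
  synchronization never uploads it.

Dataset directories are named `NNNN_<sanitized first filename>` with a
zero-padded ordinal — stable, sortable, and collision-free within a
collection. Collection and bundle names are restricted to
`[A-Za-z0-9._ -]` for cross-platform paths. Locks are advisory marker
files (owner + timestamp) honored by this software's own mutating
operations only; multi-process guarantees are out of scope.

## Coordinates and time

Spatial coordinates are signed 64-bit integers in picometers, relative
to the parent frame. Integer picometers cover ±9.2 × 10⁶ m at 1 pm
resolution — every scale from a microscope stage to a single image pixel
— with exact arithmetic: resolving a path is plain integer summation, so
composition is associative and drift-free by construction. Frames are
translation-only (no rotations or affine maps); this is a deliberate
non-goal. The root's own x, y, z are excluded from sums — the root *is*
the origin. Exactly one root per resolution path is required; paths with
zero or multiple roots are errors rather than guesses. Standard errors
(`dx, dy, dz`, non-negative pm) combine in quadrature, treating per-level
localization errors as independent; consequently the absolute error is
monotone non-decreasing in path depth.

Timestamps are 128-bit fixed point: signed 64-bit seconds since
1904-01-01 00:00:00 UT (86 400 s days, leap seconds ignored) plus an
unsigned 64-bit fraction in 2⁻⁶⁴ s units. Duration addition converts the
duration to an exact rational, scales by 2⁶⁴ and rounds half-to-even
once, then carries in integer arithmetic — dyadic durations are exact,
and the property suite checks `x + d − d = x` against a big-integer
oracle. Time is *absolute per entity*, never accumulated along the
hierarchy: the additivity of the coordinate system is spatial. Clock
calibration is injectable (`now(clock_offset=...)` with a mockable
clock); a network-time client is intentionally not part of the library.

The `scale` field is a display divisor basis: displayed = stored pm /
scale, so scale 1000 shows nanometres. The field name "multiplication
factor" in common usage and the nanometre example pull in opposite
directions; bebkit follows the example and documents it here.

## Metadata documents

One XML schema (`beb-metadata` root) with fixed sections: protocols,
user (free text + 0–5 rating), database id, coordinates, properties,
embedded, rawfiles, views. Serialization is canonical (fixed section
order, deterministic pretty-printing, UTF-8), so write∘read∘write is
byte-identical — which is what makes MD5-differential sync of annotation
files meaningful. Unknown top-level elements are preserved verbatim
across rewrites (forward compatibility). Dataset properties describe
arbitrary-dimensional data: each dimension has a name, numeric/index
kind, unit, start and spacing (equally spaced axes only) and length; the
element descriptor names the memory structure (uint8 … float64).
Attribute files are `key=value` UTF-8 lines with `#` comments; later
keys overwrite earlier ones. Frame-level annotation uses embedded keys
`frame.<n>.<key>`. Graphical annotations are stored twice on purpose:
as structured shape records (editable) and burned into a PNG (visible
to any tool).

## Protocols and the support folder

Vocabulary entries (uid, title, kind, default, optional enum list) live
in one shared library; templates store *references* (uid + optional
title/default override), so library edits propagate to exactly the
templates without a local override — propagation is by construction, and
the test suite still cross-checks incremental updates against a
recompute-from-scratch oracle. Duplicate references within a template
part are allowed (repeatable measurement blocks). Instantiated metadata
in existing bundles is never rewritten by a library edit.

The support folder (`protocols/`, `macros/`, `plugins/`, `errors/`)
synchronizes against a repository directory via `manifest.xml` (version,
compatible core range, file MD5s). Sync stages into a temporary sibling
directory and swaps with atomic renames: a failed sync leaves the prior
state; a manifest outside the compatible core range changes nothing and
reports `incompatible`.

## Macro engine

The grammar (EBNF in the module docstring) is line-oriented:
case-insensitive keywords, `$var` interpolation, comparison operators
`= ≠ < > ≤ ≥` (ASCII spellings accepted), `+ − × ÷` on numbers, `#`
comments, no parentheses or user functions. Modules are FIFO queues:
SEND enqueues and continues; queues drain cooperatively at instruction
boundaries (and synchronously inside CALL/WAITIDLE), so each module
observes commands strictly in send order while the global interleaving
stays unconstrained. CALL stores the handler's reply in `_reply` and
times out (default 60 s, configurable). Registration probes the minimal
command set (`status`, `noop`, `abort`) and refuses handlers that reject
it. RESERVE/RELEASE guard named resources with real locks, released on
any exit path. WHILE loops run under a step budget (default 10⁶) and
abort with a budget error instead of hanging. SLEEP advances the
injectable clock, so scheduled runs test instantly. PROMPT consults a
scripted responder and fails fast headless without one.

Every instruction and module command is logged *before* execution
(write-ahead), so a crash mid-command still leaves the command on
record; error reports route through three tolerance levels — strict
(anything aborts), tolerant (warnings continue, errors abort),
permissive (log and continue; fatal always aborts).

The cron table (`HH:MM [MON,TUE,…] name`) fires each entry at most once
per matching minute, in table order; a missing macro is a logged error
that does not block other entries. The TCP application server speaks a
deliberately simple newline protocol (one instruction, `RUN <macro>` or
`GET <var>` per line; `OK …`/`ERR …` replies); it is this package's own
documented dialect.

## Plug-in ordering

Activation is Kahn's algorithm with the ready set as a priority queue on
(precedence band, name): data-type definitions (viewportType) first,
libraries second, everything else after, lexicographic within ties —
every plan is reproducible and a valid topological order. Disabled
plug-ins, incompatible core requirements, malformed descriptors, missing
dependencies and cycle members are skipped with a reason, and skipping
propagates to dependents (no active plug-in has a skipped dependency).
Note the two guarantees — topological order and band order — are jointly
satisfiable only because legal dependencies point toward equal-or-lower
bands (a library may depend on a viewportType, never the reverse);
bebkit validates viewports (exactly one viewportType dependency) and
otherwise trusts descriptor typing.

## Database synchronization

One experiment per bundle (id = bundle name, keeping repeat syncs
idempotent against one record), one sample per collection (id = path
slug; the parent sample is recorded, enabling recursive download), and
per sample one dataset per local dataset plus a `_collection`
pseudo-dataset for collection-level annotation files — every stored file
carries the experiment → sample → dataset provenance chain. The sync
sequence is: verify local integrity (abort before any upload on
failure) → ensure experiment → ensure samples, writing database ids back
into local metadata *before* diffing → MD5-diff → upload changed files
only. Download reverses it: recreate the four-folder layout, fetch
RawData and Annotations, regenerate Cache locally, verify. The store is
a minimal contract (put/get/list/stat-with-md5) implemented by a local
directory mock; a real database wire protocol is out of scope.

## The demo generator

`generate_demo_bundle` emulates a correlative workflow at desk scale:
LM frames are 2-D Gaussian spots (σ 2–4 px, linear drift of 50 000
pm/frame at 100 nm/pixel) over Poisson-distributed background; the
selected cell's position converts to pm and becomes the lysis
sub-frame's offset; EM images are fields of small dark disks
("particles") on a bright background at 1 nm/pixel; a sine-plus-noise
fluorescence trace is stored as an equally spaced wave. Defaults (5
frames, 60 s interval, 64 px images, 3 cells, 2 EM images) keep the
bundle a few tens of kilobytes. All randomness derives from the seed and
all timestamps from a fixed start instant, so one seed yields a
byte-identical bundle (ZIP member mtimes are pinned for this). What the
demo does *not* emulate: real point-spread functions, detector noise
models, stage hysteresis, rotation/shear between frames, or instrument
metadata richness — passing tests show the bookkeeping (layout,
checksums, coordinate algebra, sync) is correct, not that any image
analysis would succeed on real data.

## Numerical choices and limitations

- Preview normalization is linear min→max (constant images map to
  mid-grey 128); percentile auto-contrast was considered and rejected to
  keep previews a deterministic function of the data.
- The power spectrum view is `log(1 + |F|)`, zero frequency centered,
  normalized by its maximum; the log constant 1 is fixed. The magnitude
  spectrum's translation invariance and Parseval's identity are tested.
- The viridis-like LUT is a 256-entry linear interpolation through ten
  anchor colors; LUT mapping clips to the given range so values at or
  below the low bound hit entry 0 and at or above the high bound entry
  255.
- Pixel convention is row-major (y, x), origin top-left, everywhere.
- Duration rounding is half-to-even at 2⁻⁶⁴ s; non-dyadic durations are
  therefore exact to ±2⁻⁶⁵ s.
- Wave CSV import accepts one numeric column with `# key = value` header
  comments; malformed rows fail with their line number.
- Known limitations: no affine frame transforms, no OS-level locking, no
  authentication on the TCP server or store, no log rotation, no hot
  plug-in reload, and vendor container formats (e.g. proprietary
  microscope files) are handled only through the generic import path
  plus sidecar attribute files.
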