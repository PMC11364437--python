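# Methods

## The indexing model

Generalist repositories index dataset-level metadata (title, description)
written free-form by depositors; they do not index file contents, and files
inside zip archives are invisible to their search. `mdscout` therefore
treats the *file extension* as the primary signal of MD relevance and the
*dataset* as the unit of curation, under the working assumption that files
deposited together belong to one research project.

The pipeline has three phases:

1. **explore** — for every (extension, keyword) query, collect all dataset
   ids each repository reports, traversing every result page and deduping.
   Extensions unique to MD software (`.mdp`, `.gro`, `.xtc`, `.tpr`,
   `.psf`, `.parm7`, …) are queried bare; ambiguous ones (`.log`, `.top`,
   `.itp`, `.zip`) only in conjunction with curated keywords
   ("molecular dynamics", "gromacs", "martini", …). The shipped lists in
   `mdscout/data/query.yml` are defaults and fully overridable.
2. **expand** — fetch the latest version of each candidate dataset and
   catalogue every file. Zip contents come from the repository's HTML
   preview: Zenodo lists at most 1000 members (flagged `truncated`),
   Figshare lists all, OSF has no preview, so OSF archives stay opaque.
   File sizes come from API metadata / previews; indexing never downloads
   file content.
3. **clean** — drop datasets sharing no file type with the curated list.
   Archive extensions themselves (`zip`) are marked `archive: true` in the
   query config and excluded from this target list: archives are discovery
   vehicles, and counting them as MD file types would make every
   keyword-matched archive of irrelevant documents survive cleaning.

Aggregates stored per dataset: `n_files` counts plain files,
`n_files_within_zip` counts previewed members, and `total_size_bytes` sums
plain files only — members live inside archives that are already counted,
so adding their sizes would double-count. GB means 10⁹ bytes, matching
repository UIs.

All network access goes through a swappable transport. The fixture
transport replays a recorded tree addressed by a hash of
(repository, endpoint, parameters), which makes harvests byte-reproducible;
the live transport is a thin urllib layer with per-repository rate
limiting and three exponential-backoff attempts. When two snapshots merge,
the newer harvest wins per dataset (file rows replaced atomically); a
version tie on publication date resolves to the lexicographically greater
version tag and is logged.

## File parsing

**.gro** is fixed-column: `%5d%-5s%5s%5d` then three `%8.3f` coordinates
(nm) and optionally three `%8.4f` velocities (nm/ps). Fields are sliced by
character position because deposited files routinely have large residue
numbers or five-character names that merge adjacent columns, which
whitespace splitting misparses. Velocities are detected from line length
(≥ 68 characters). A file declaring more atoms than it holds raises a
truncation error reporting expected vs found counts.

**.mdp** parsing is total: `;` starts a comment, keys are lowercased with
`-` mapped to `_` (Gromacs accepts either), the last occurrence of a
repeated key wins, and lines that fit no rule are counted as warnings
rather than raised. Typed fields (`dt`, `nsteps`, `ref_t`, `integrator`,
raw coupling strings) are left absent when their text does not parse;
`dt ≤ 0` is treated as absent. Only `ref_t` provides temperatures;
`gen_temp` and annealing schedules are ignored because each file is
summarized by one starting temperature.

**.xtc** is big-endian XDR: per frame a header (magic 1995, atom count,
step, time), nine box floats, then the coordinate block — plain floats for
≤ 9 atoms, otherwise the compressed payload prefixed by its byte count.
The reader counts frames by seeking over payloads without decompressing,
so multi-gigabyte trajectories scan at I/O speed. A trailing partial frame
sets `truncated` and is not counted; a bad magic number on frame 0 means
"not an XTC", mid-stream it reports the corrupt frame index. The package
never writes compressed payloads; the compressed *read* path is validated
against trajectories written by MDAnalysis in the test suite.

## Derived annotations

- **Engine assignment** is a pure extension lookup
  (`mdscout/data/engines.yml`, overridable). NAMD and CHARMM share most
  extensions and form one joint bucket. `.top` maps to Gromacs even though
  CHARMM-style topologies exist under the same extension; the trade-off is
  noted in the data file's scope, not silently resolved per file.
- **Composition** classifies each atom by its residue name through
  `mdscout/data/residues.yml`. Names shared between ions and one-letter
  nucleotide codes (`K`, `NA`) resolve to water/ions by exact-name
  priority — flagged in the dictionary header. The group label joins the
  non-empty categories among protein/lipid/nucleic/glucid/other with `+`;
  systems holding only water/ions form their own class; empty or fully
  unrecognized systems are "other".
- **Resolution**: `dt ≥ 0.01 ps` (10 fs) ⇒ coarse-grain, the boundary
  inclusive on the coarse-grain side since no atomistic force field runs
  at 10 fs; `dt` absent ⇒ unknown. The classification depends only on
  `dt`, never on `nsteps`.
- **Simulation time** is the planned `dt × nsteps` — the setup intent, not
  evidence the run finished.
- **Coupling normalization** matches case- and `-`/`_`-insensitively
  against the thermostats {no, berendsen, nose-hoover, andersen,
  andersen-massive, v-rescale} and barostats {no, berendsen, c-rescale,
  parrinello-rahman, mttk}; absent or `no` becomes `none`, anything else
  `invalid`. Invalid values stay in the record but are excluded from flow
  analytics by default; (`none`, `none`) pairs are kept — they are the
  no-coupling (minimization/ion-placement style) class.
- **Headline temperature** is the first `ref_t` group. Multi-group files
  nearly always repeat one value; `max` and `mean` reductions are exposed
  as a switch for sensitivity checks.
- **Production filter**: integrator `md` or `sd` and strictly more than
  1 ns planned — excludes most minimization and equilibration setups.

Time-distribution reporting uses bands (1, 50] ns, (50, 1000] ns and
> 1 µs, with half-open edges owned by the lower band boundary; the band
edges are module constants, and the coarse-grain share of the top band is
reported as a fraction of its population.

## Search engine

Substring matching (no stemming, no fuzziness) keeps ranking auditable:
the score is the number of distinct keywords found across title,
description and file names; ties order by newest publication date, then
dataset id. All filters are conjunctive, so adding one can only shrink the
result set. TSV export writes one row per matching file with a link back
to the source repository; embedded tabs/newlines are replaced by spaces so
the column count survives any description. Any web front end is a thin
optional wrapper over `explorer.search`; all logic is headless.

## The synthetic corpus and what it shows

`fixtures.gen_corpus` emulates the statistical structure of deposited MD
data: a Gromacs-dominated engine mixture with NAMD/CHARMM, AMBER and
DESMOND minorities; compositions drawn from protein/lipid-heavy templates;
all-atom time steps of 1–4 fs vs coarse-grain 10–30 fs with coarse-grain
setups weighted toward the longest planned times; temperatures peaked at
298–310 K with minor mass at 100–280 K and 400–800 K; and zip-heavy
datasets in which archive members outnumber plain files about sevenfold
corpus-wide (per-archive member counts are doubled relative to that factor
because only part of the datasets carry archives). Each repository also
receives one decoy dataset, discoverable through keyword+archive queries
but containing no MD file type, which the clean step must remove. The
default corpus (7 Zenodo + 5 Figshare + 3 OSF datasets, a few hundred
files) keeps a 100-seed full-loop run in tens of seconds; counts scale
through `CorpusSpec`.

The manifest is computed at generation time by direct enumeration over the
planted truth, with its own private copies of the engine table, the
coarse-grain cutoff and the band edges — never by calling the pipeline.
Tests assert *exact* equality between pipeline output and manifest.

What passing does and does not show: the corpus exercises every dialect,
format quirk the generator plants (merged columns, spelling variants,
archives, decoys, truncated streams) and every analytics rule, but it
cannot certify behaviour against the real repositories' live APIs, against
preview markup drift, or against the long tail of malformed deposited
files; those paths degrade (skip-and-log, warning counts, absent fields)
rather than abort, by design.

## Numerical and degenerate-input choices

Coordinates are compared at the format's 3-decimal precision. ECDF steps
at tied values take the fraction ≤ the value. Temperature bins are
left-closed right-open, aligned at multiples of the bin width. Extension
top-k ties break alphabetically. The one-trajectory-per-dataset sample
prefers the lexicographically first plain file, falling back to the first
archive member. Empty inputs are legal throughout: an empty index cleans
to an empty index, an empty byte stream is a zero-frame trajectory, a
zero-atom `.gro` is valid.

## Known limitations

- Live-mode transport is deliberately thin (no OAuth, no resumable
  downloads); serious live harvests should checkpoint per dataset.
- Repository response fixtures model simplified versions of the real API
  dialects; field names match current public APIs but not exhaustively.
- OSF archive contents are structurally unknowable without download.
- No `.tpr`/`.trr`/`.edr`/topology parsing (counted by extension only),
  no force-field identification, no biased-vs-unbiased trajectory
  detection.
- The deposited-snapshot reproduction test needs a local copy of the
  published Parquet tables and is skipped without it.
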