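# mdscout

Mine the *dark matter* of molecular dynamics: MD simulation files that sit
in generalist data repositories (Zenodo, Figshare, OSF) — technically
public, but unindexed, uncurated and hard to search. `mdscout` finds those
datasets, catalogues every file they contain, parses the Gromacs formats
among them, and turns the result into a searchable, exportable index.

## What it does

**Explore and Expand (Ex²) indexing.** Repository metadata is too thin for
plain keyword search, so discovery is driven by *file types*: in the
*explore* phase, each repository is queried for datasets holding
characteristic MD extensions (`.mdp`, `.gro`, `.xtc`, `.psf`, `.parm7`, …),
optionally combined with curated keywords for ambiguous extensions
(`.log`, `.top`, `.zip`, …). In the *expand* phase every file of each hit
dataset is catalogued — including members of zip archives, read from the
repository's HTML content preview (Zenodo truncates these at 1000 entries;
OSF offers none). A final *clean* step drops datasets that share no file
type with the curated list, removing archive-borne false positives.
Datasets, never single files, are the unit of inclusion.

**Gromacs file mining.** Native readers for

- `.gro` — fixed-column coordinates, sliced by character position so files
  with merged columns still parse; yields the atom count and a per-residue
  census classified into protein / lipid / nucleic / glucid / water-ions /
  other via an overridable residue dictionary;
- `.mdp` — total `key = value` parser with Gromacs key normalization
  (case- and `-`/`_`-insensitive); yields integrator, time step `dt` (ps),
  `nsteps`, reference temperatures and raw coupling values;
- `.log` — Gromacs version and command line, when present;
- `.xtc` — frame and particle counting of the XDR binary trajectory by
  seeking over compressed payloads, never decompressing them.

**Derived annotations.** Planned simulation time `dt × nsteps`; model
resolution (time step ≥ 10 fs ⇒ coarse-grain — no atomistic force field
integrates that coarsely, while Martini-style models routinely use
20–30 fs); canonical thermostat/barostat values checked against the
documented Gromacs options; a production-run filter (`md`/`sd` integrator
and > 1 ns); a headline temperature per file.

**Analytics.** Per-repository dataset/file/size statistics with a totals
row, engine and extension distributions, empirical CDFs, composition
(upset) group counts, thermostat–barostat flow counts, temperature
histograms, and a one-trajectory-per-dataset sample.

**Search engine.** Case-insensitive substring search over titles,
descriptions and file names with conjunctive repository / engine /
extension / date / size filters, ranked by distinct keywords matched, and
TSV export with one row per matching file.

**Synthetic corpora.** `mdscout.fixtures` generates complete mock
repositories — search API pages, dataset records, zip-preview HTML, real
downloadable Gromacs files — together with a ground-truth manifest computed
by direct enumeration, so the whole pipeline is testable offline.

## Worked example

Everything below runs offline against a generated corpus:

```sh
mdscout gen-fixtures --seed 1 --out corpus
# corpus -> corpus (12 MD-relevant datasets; manifest.json written)

mdscout index --out snap --fixtures corpus
# indexed 12 datasets, 360 files -> snap

mdscout analyze snap --report table1 --out table1.tsv
```

`table1.tsv` (the per-repository statistics):

```
repository  n_datasets  first_dataset_date  latest_dataset_date  n_files  total_size_gb  n_zip_files  n_files_within_zip  n_total_files
figshare    4           2014-01-07          2022-12-28           16       0.000218633    4            230                 246
osf         2           2013-10-06          2014-04-22           8        6.735e-06      0            0                   8
zenodo      6           2013-01-21          2022-12-25           19       8.713e-05      2            87                  106
total       12          2013-01-21          2022-12-28           43       0.00031249...  6            317                 360
```

Three planted decoy datasets (discovered through keyword+zip queries but
containing no MD file type) were removed by the cleaning step; 317 of the
360 catalogued files live inside zip archives — the members-outnumber-plain
imbalance the generator plants on purpose. Engine assignment over the same
snapshot (`--report engines`) counts 258 Gromacs files, 3 NAMD/CHARMM, 1
DESMOND and 98 unassigned; the thermostat–barostat flows (`--report mdp
--fixtures corpus`) are dominated by `v-rescale`/`parrinello-rahman` (14
files) with 37 files carrying neither coupling — minimization-style setups.

Searching the snapshot:

```sh
mdscout search snap --keywords martini --ext gro --out hits.tsv
# 2 datasets, 33 file rows -> hits.tsv
```

Each row carries repository, dataset id, DOI, a link back to the original
repository page, and the file's name/extension/size/zip provenance.

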