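# Curated file types and keywords driving the explore phase.
# `keyword_required: false` means the extension alone is trusted to be
# MD-specific; ambiguous extensions are combined with every keyword.
# `archive: true` marks discovery-only container formats that never count
# as MD file types during the cleaning step.
# Replaceable: pass --query-config to use a custom list.
file_types:
  - {ext: mdp, keyword_required: false}
  - {ext: gro, keyword_required: false}
  - {ext: xtc, keyword_required: false}
  - {ext: trr, keyword_required: false}
  - {ext: tpr, keyword_required: false}
  - {ext: edr, keyword_required: false}
  - {ext: psf, keyword_required: false}
  - {ext: prmtop, keyword_required: false}
  - {ext: parm7, keyword_required: false}
  - {ext: cms, keyword_required: false}
  - {ext: top, keyword_required: true}
  - {ext: itp, keyword_required: true}
  - {ext: log, keyword_required: true}
  - {ext: zip, keyword_required: true, archive: true}
keywords:
  - molecular dynamics
  - md simulation
  - gromacs
  - namd
  - charmm
  - amber
  - martini
  - coarse-grain
  - force field
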