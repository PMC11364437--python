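# File-extension -> MD-engine assignment table.
# NAMD and CHARMM share most extensions and cannot be told apart, so they
# form one joint bucket. Anything unlisted maps to "unknown".
gromacs: [gro, mdp, xtc, trr, tpr, itp, top, edr, ndx, cpt]
amber: [prmtop, parm7, inpcrd, rst7, mdcrd, frcmod]
namd/charmm: [psf, dcd, prm, rtf, str, coor, vel, xsc]
desmond: [cms, mae]
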