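# Experimental structure inputs

The consensus-contact reproduction for the real G_A/G_B system reads the
eight experimental PDB entries from this directory as lower-case
`<id>.pdb` files:

* G_A fold conformers: `2fs1.pdb`, `2jws.pdb`, `2kdl.pdb`, `2lhc.pdb`
* G_B fold conformers: `1pga.pdb`, `2jwu.pdb`, `2kdm.pdb`, `2lhd.pdb`

These files are experimental data deposited in the Protein Data Bank and
are not redistributed with this package; obtain them from the PDB and
place them here.  Structure download automation is deliberately out of
scope — all structure inputs are provided by path.
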