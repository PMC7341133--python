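# data/

Place a local copy of PDB entry 5B1A (bovine cytochrome c oxidase,
1.5 Å crystal structure) here as `5B1A.pdb` or `5B1A.cif` to enable the
structural distance acceptance targets:

    curl -O https://files.rcsb.org/download/5B1A.pdb

The file is not bundled because the build environment had no access to
the PDB; nothing in the package downloads it automatically.
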