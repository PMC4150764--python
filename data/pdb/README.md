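# Optional crystal-structure inputs

The test suite includes checks against the deposited apo (PDB 1UI5) and
operator-bound (PDB 4PXI) CprB structures. They are not bundled and are never
downloaded automatically. To enable those tests, place the files here as:

    data/pdb/1ui5.pdb
    data/pdb/4pxi.pdb

(e.g. from https://files.rcsb.org/download/1UI5.pdb). Without them the
corresponding tests are skipped; every synthetic-data check runs regardless.
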