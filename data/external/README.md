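# External reference structures

Not distributed with the package. To run the crystallographic acceptance
checks, download:

```sh
curl -O https://files.rcsb.org/download/2OMF.pdb   # OmpF porin (7 x 11 Å constriction)
curl -O https://files.rcsb.org/download/1J4N.pdb   # aquaporin-1 (~2.7 Å constriction)
```

into this directory (lower- or upper-case filenames are accepted), then run
`python -m pytest tests/test_acceptance.py::TestReferenceStructures`.
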