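# Deposited plasmid sequences

The published-family checks in `tests/test_acceptance.py` and any
pipeline run on the real family need the five deposited plasmid
sequences as plain FASTA, one file per accession:

    data/accessions/FR746101.fasta   # PL6A   (6129 nt)
    data/accessions/FR746102.fasta   # PL6B   (6056 nt)
    data/accessions/LT984491.fasta   # pBAJ9-6 (6213 nt)
    data/accessions/LT984489.fasta   # pLT53-7 (7045 nt)
    data/accessions/LT991975.fasta   # pLTMV-6 (5884 nt)

With network access they can be fetched from ENA, e.g.:

    for acc in FR746101 FR746102 LT984491 LT984489 LT991975; do
        curl -s "https://www.ebi.ac.uk/ena/browser/api/fasta/$acc" \
            > data/accessions/$acc.fasta
    done

The sequences are not redistributed with this repository; everything
else in the test suite is generated synthetically at run time.
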