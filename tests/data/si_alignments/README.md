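Place the published supplementary gene alignments here to enable the
observed-statistic acceptance checks:

    rnap2.fasta (or .phy)   RNA polymerase II    (80 taxa x 272 columns)
    tf2b.fasta              TFIIB
    fen.fasta               Flap endonuclease
    pcna.fasta              PCNA

These files are not redistributed with the package; the corresponding tests
fail with a clear message until the files are provided.
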