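>tRNA-Phe yeast tRNA-Phe transcript (76 nt)
GCGGAUUUAGCUCAGUUGGGAGAGCGCCAGACUGAAGAUCUGGAGGUCCUGUGUUCGAUC
CACAGAAUUCGCACCA
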