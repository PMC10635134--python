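# Site labels for methyl-bearing ARNT PAS-B residues observed in the example
# peak tables: cavity-lining, surface, or outlier (synthetic stand-in).
residue	site
396	cavity
408	cavity
415	cavity
418	cavity
423	cavity
425	cavity
457	cavity
458	surface
381	outlier
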