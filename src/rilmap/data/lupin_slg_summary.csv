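group,n_markers,n_loci,length_cm,n_scaffolds,scaffold_span_bp
SLG-1,1498,235,234.3,763,12956288
SLG-2,1496,140,156.7,724,11025395
SLG-3,414,151,149.0,236,4368678
SLG-4,814,120,144.2,400,6428848
SLG-5,785,143,101.9,365,6243667
SLG-6,242,73,89.0,129,2743736
SLG-7,218,81,86.5,114,2326261
SLG-8,539,64,85.0,289,4760577
SLG-9,299,95,83.5,155,2970440
SLG-10,232,104,82.6,138,2151365
SLG-11,690,85,82.2,344,6059460
SLG-12,246,34,64.9,143,2103598
SLG-13,266,36,52.2,155,2321041
SLG-14,102,40,51.1,57,1150524
SLG-15,69,23,34.5,32,631989
SLG-16,81,23,33.3,47,733299
SLG-17,82,24,32.4,40,766926
SLG-18,68,16,26.6,28,733186
SLG-19,23,16,20.6,13,572743
SLG-20,82,14,19.4,42,703582
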