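# Small demonstration scan (finishes in ~1 minute).
# Omitted keys take the study defaults: sizes 10:50:1, connectances
# 0.10:0.48:0.02, replicates 250, dt 0.01, phases 1000/1000, window 20.
[scan]
sizes = 10,15,20
connectances = 0.12,0.20,0.28
replicates = 2
master_seed = 1
dt = 0.01
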