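# hmmscan profile name -> semaplex domain vocabulary.
# Edit freely: Pfam profile naming drifts between releases.
Sema: SEMA
PSI: PSI
TIG: IPT
IPT: IPT
fn3: FN3
FN3: FN3
TSP_1: TSP1
I-set: IG
Ig_2: IG
ig: IG
SEA: SEA
RasGAP: RASGAP
Pkinase_Tyr: TYRKIN
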