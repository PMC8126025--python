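# Proteins with prior plasma-membrane localization evidence whose FFE
# profiles instead overlapped the anodic tonoplast window (samples 13-19).
# agi: best A. thaliana BLAST hit accession (blank where not established).
protein_id	agi	annotated_compartment
NHX7	At2g01980	PM
NCL	At1g53210	PM
AMT1-1	At4g13510	PM
TauE		PM
ABCG40	At1g15520	PM
ABCC4	At2g47800	PM
ENT1	At1g70330	PM
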