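"""Single home of every tunable numeric threshold.

Stage modules take these as keyword defaults; nothing else in the package
hard-codes them, so loosening a cut-off (recommended for sensitive
exploratory runs) is a one-place change.
"""

#: Candidate retention: best alignment H-value must strictly exceed this.
DEFAULT_H_THRESHOLD = 0.36
#: Toxin/antitoxin protein length window, inclusive (amino acids).
DEFAULT_LEN_MIN = 30
DEFAULT_LEN_MAX = 500
#: IS/transposon flanking association window, strict upper bound (bp).
DEFAULT_FLANK_BP = 5000
#: Mash distance below which two MGEs count as similar (strict).
DEFAULT_MASH_THRESHOLD = 0.01
#: MinHash sketch parameters (Mash defaults) and fixed hash seed.
DEFAULT_K = 21
DEFAULT_SKETCH_SIZE = 1000
DEFAULT_HASH_SEED = 42
#: Permissive raw E-value ceiling for alignment hits (pre-filter only).
DEFAULT_EVALUE_CEILING = 0.01
#: Profile-HMM domain hit E-value threshold.
DEFAULT_HMM_EVALUE = 1e-5
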