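"""Reference values for the *Forsythia suspensa* Fsus-CHAU T2T assembly.

The published per-chromosome functional-centromere (CENH3-binding) sizes and
the assembly size, used as inputs to the summary arithmetic (the genome
itself is not required for that computation).
"""

# Cen size (Mb) for chromosomes 1..14
FSUS_CENTROMERE_SIZES_MB: list[float] = [
    1.4, 0.8, 0.4, 1.5, 0.6, 1.5, 0.5, 0.8, 1.0, 1.0, 0.8, 1.4, 0.8, 0.4,
]

FSUS_GENOME_SIZE_MB: float = 688.79

FSUS_N_CHROMOSOMES: int = 14

# centromeric satellite monomer unit sizes (bp) of the four CentFs families
FSUS_CENTFS_UNIT_SIZES: list[int] = [356, 365, 530, 732]
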