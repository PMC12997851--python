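"""Bundled compositions of commercial mock-community DNA standards.

The two standards used throughout the examples and tests are the
ZymoBIOMICS Microbial Community DNA Standard II (Log Distribution; ten
members spanning roughly six decades of genomic-DNA mass) and the
ZymoBIOMICS Gut Microbiome Standard (21 members, including five
*Escherichia coli* strains, two fungi and one archaeon). Compositions are
taken from the vendor's published product specifications as genomic-DNA
mass fractions together with nominal genome sizes; genome-copy relative
abundances follow as ``mass / genome_size``, normalized.

On genome-copy relative abundances the log-distributed standard has a
Simpson dominance (Σp²) of ≈0.90 — a single dominant member — while the
gut standard is comparatively even at ≈0.11.
"""

from __future__ import annotations

#: species -> (genomic DNA mass %, nominal genome size in Mb)
LOG_DISTRIBUTED_DNA_STANDARD: dict[str, tuple[float, float]] = {
    "Listeria monocytogenes": (89.1, 2.992),
    "Pseudomonas aeruginosa": (8.9, 6.792),
    "Bacillus subtilis": (0.89, 4.045),
    "Saccharomyces cerevisiae": (0.89, 12.1),
    "Escherichia coli": (0.089, 4.875),
    "Salmonella enterica": (0.089, 4.760),
    "Lactobacillus fermentum": (0.0089, 1.905),
    "Enterococcus faecalis": (0.00089, 2.845),
    "Cryptococcus neoformans": (0.00089, 19.05),
    "Staphylococcus aureus": (0.000089, 2.730),
}

GUT_MICROBIOME_STANDARD: dict[str, tuple[float, float]] = {
    "Faecalibacterium prausnitzii": (14.0, 3.09),
    "Veillonella rogosae": (14.0, 2.16),
    "Roseburia hominis": (14.0, 3.3),
    "Bacteroides fragilis": (14.0, 5.2),
    "Prevotella corporis": (6.0, 3.0),
    "Bifidobacterium adolescentis": (6.0, 2.2),
    "Fusobacterium nucleatum": (6.0, 2.3),
    "Lactobacillus fermentum": (6.0, 1.9),
    "Clostridioides difficile": (1.5, 4.2),
    "Akkermansia muciniphila": (1.5, 2.7),
    "Methanobrevibacter smithii": (0.1, 1.7),
    "Salmonella enterica": (0.01, 4.8),
    "Enterococcus faecalis": (0.001, 2.9),
    "Clostridium perfringens": (0.0001, 3.3),
    "Escherichia coli B1109": (2.8, 4.9),
    "Escherichia coli B766": (2.8, 4.9),
    "Escherichia coli B2207": (2.8, 4.9),
    "Escherichia coli B3008": (2.8, 4.9),
    "Escherichia coli B2587": (2.8, 4.9),
    "Candida albicans": (1.5, 14.3),
    "Saccharomyces cerevisiae": (1.4, 12.1),
}


def genome_copy_fractions(standard: dict[str, tuple[float, float]]) -> dict[str, float]:
    """Genome-copy relative abundances from (mass %, genome size) pairs."""
    copies = {name: mass / size for name, (mass, size) in standard.items()}
    total = sum(copies.values())
    return {name: value / total for name, value in copies.items()}


def log_standard_copy_fractions() -> dict[str, float]:
    return genome_copy_fractions(LOG_DISTRIBUTED_DNA_STANDARD)


def gut_standard_copy_fractions() -> dict[str, float]:
    return genome_copy_fractions(GUT_MICROBIOME_STANDARD)
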