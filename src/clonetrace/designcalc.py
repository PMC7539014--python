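"""Barcoding-experiment design arithmetic.

Small, exact calculators for the quantities that size a cellular-barcoding
experiment: how many clones a transduction yields at a given multiplicity of
infection, how many cells represent each barcode, and how many genome
equivalents (hence cells) a PCR input mass covers. Rounding conventions are
explicit parameters so report text can match a protocol's printed precision.
"""

from __future__ import annotations

import math

__all__ = [
    "MOUSE_DIPLOID_GENOME_PG",
    "expected_transduced_clones",
    "cells_per_barcode",
    "genome_equivalents",
    "cells_analyzed",
    "design_sheet",
]

# Mass of one diploid mouse genome in picograms (~3.3 pg per haploid genome).
MOUSE_DIPLOID_GENOME_PG = 6.6


def expected_transduced_clones(n_cells: int, moi: float, model: str = "linear") -> float:
    """Expected number of uniquely barcoded clones after transduction.

    ``linear`` is the usual back-of-envelope n_cells * MOI; ``poisson``
    accounts for cells receiving multiple integrations,
    n_cells * (1 - exp(-MOI)). The two agree as MOI -> 0.
    """
    if moi < 0:
        raise ValueError("moi must be >= 0")
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    if model == "linear":
        return n_cells * moi
    if model == "poisson":
        return n_cells * (1.0 - math.exp(-moi))
    raise ValueError(f"unknown model {model!r}; expected 'linear' or 'poisson'")


def cells_per_barcode(total_cells: int, n_barcodes: int) -> float:
    """Average number of cells carrying each barcode."""
    if n_barcodes < 1:
        raise ValueError("n_barcodes must be >= 1")
    return total_cells / n_barcodes


def _round_to(value: float, round_to: int | None) -> float:
    if round_to is None:
        return value
    if round_to < 1:
        raise ValueError("round_to must be a positive integer")
    return round(value / round_to) * round_to


def genome_equivalents(
    dna_mass_ng: float,
    genome_mass_pg: float = MOUSE_DIPLOID_GENOME_PG,
    round_to: int | None = None,
) -> float:
    """Number of (diploid) genome copies in a DNA mass.

    1000 * mass[ng] / genome mass[pg]; e.g. 80 ng of mouse tumor DNA is
    ~12,100 genomes at the nearest hundred.
    """
    if dna_mass_ng < 0:
        raise ValueError("dna_mass_ng must be >= 0")
    if genome_mass_pg <= 0:
        raise ValueError("genome_mass_pg must be > 0")
    return _round_to(1000.0 * dna_mass_ng / genome_mass_pg, round_to)


def cells_analyzed(
    n_reactions: int, genomes_per_reaction: float, round_to: int | None = None
) -> float:
    """Cells whose barcodes are interrogated across parallel PCR reactions."""
    if n_reactions < 0 or genomes_per_reaction < 0:
        raise ValueError("inputs must be >= 0")
    return _round_to(n_reactions * genomes_per_reaction, round_to)


def design_sheet(
    n_cells: int = 200_000,
    moi: float = 0.1,
    expanded_cells: int = 100_000_000,
    injected_cells: int = 1_000_000,
    dna_mass_ng: float = 80.0,
    n_reactions: int = 8,
    genome_mass_pg: float = MOUSE_DIPLOID_GENOME_PG,
) -> str:
    """Plain-text design sheet tying the calculators together."""
    clones = expected_transduced_clones(n_cells, moi)
    clones_poisson = expected_transduced_clones(n_cells, moi, "poisson")
    genomes = genome_equivalents(dna_mass_ng, genome_mass_pg, round_to=100)
    cells = cells_analyzed(n_reactions, genomes, round_to=1000)
    lines = [
        "Barcoding design sheet",
        f"  transduced cells          : {n_cells:,} at MOI {moi}",
        f"  expected barcoded clones  : {clones:,.0f} (Poisson: {clones_poisson:,.1f})",
        f"  cells/barcode, expanded   : {cells_per_barcode(expanded_cells, round(clones)):,.0f}"
        f" ({expanded_cells:,} cells)",
        f"  cells/barcode, injected   : {cells_per_barcode(injected_cells, round(clones)):,.0f}"
        f" ({injected_cells:,} cells)",
        f"  genome equivalents/rxn    : {genomes:,.0f} ({dna_mass_ng} ng at {genome_mass_pg} pg/genome)",
        f"  cells analyzed/sample     : {cells:,.0f} ({n_reactions} reactions)",
    ]
    return "\n".join(lines)
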