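"""Small reporting helpers for summary-table arithmetic.

These reproduce the rounded quantities that appear in assembly and
annotation summary tables: mean sequence length from a sequence count
and total length, and annotation rates as percentages.
"""

from __future__ import annotations

__all__ = ["mean_sequence_length", "annotation_percentage"]


def mean_sequence_length(total_length_bp: int, n_sequences: int, ndigits: int = 2) -> float:
    """Average sequence length in bp, rounded for table display."""
    if n_sequences < 1:
        raise ValueError("need at least one sequence")
    if total_length_bp < 0:
        raise ValueError("total length must be non-negative")
    return round(total_length_bp / n_sequences, ndigits)


def annotation_percentage(n_annotated: int, n_total: int, ndigits: int = 2) -> float:
    """Share of annotated sequences as a percentage (e.g. 39.44)."""
    if n_total < 1:
        raise ValueError("need at least one sequence")
    if not 0 <= n_annotated <= n_total:
        raise ValueError("annotated count must lie within [0, total]")
    return round(100.0 * n_annotated / n_total, ndigits)
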