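"""Small shared nucleotide utilities: alphabets, IUPAC codes, reverse complement."""

from __future__ import annotations

# Canonical alphabet used throughout; anything else is normalised to N on ingest.
CANONICAL = set("ACGTN")

# IUPAC degenerate nucleotide codes -> the set of concrete bases each matches.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "W": "AT", "S": "CG",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans(
    "ACGTRYWSKMBDHVN",
    "TGCAYRWSMKVHDBN",
)


def revcomp(seq: str) -> str:
    """Reverse complement, IUPAC-aware (R<->Y, K<->M, W/S self-complementary)."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize(seq: str) -> tuple[str, int]:
    """Uppercase, strip alignment gaps and map non-ACGTN letters to N.

    Returns the normalised sequence and the number of ambiguity codes
    (anything outside ACGTN) that were converted to N.
    """
    s = seq.upper().replace("-", "").replace(".", "")
    n_ambig = sum(1 for c in s if c not in CANONICAL)
    if n_ambig:
        s = "".join(c if c in CANONICAL else "N" for c in s)
    return s, n_ambig


def base_matches(read_base: str, primer_code: str) -> bool:
    """True if a concrete read base satisfies an IUPAC primer code.

    N in the read matches nothing: it always counts as a mismatch.
    """
    if read_base == "N":
        return False
    return read_base in IUPAC.get(primer_code, "")
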