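"""Programmatically built list of valid drug-like SMILES.

Used by the synthetic generator's SMILES mode so curation and
featurization paths can be exercised without inventing chemistry at run
time.  Structures are simple chains and mono-/di-substituted benzenes,
valid by construction, plus a few stereoisomer pairs that collapse to the
same non-stereospecific canonical SMILES (exercising duplicate
aggregation).
"""

from __future__ import annotations

from functools import lru_cache

# groups that can start a SMILES string and bond to an aromatic carbon
_PREFIXES = (
    "C", "CC", "CCC", "CC(C)C", "O", "OC", "OCC", "N", "NC",
    "Cl", "F", "Br", "N#C", "C(=O)O", "C(=O)OC", "C(=O)N",
)
# groups valid inside a ring-substituent branch, e.g. c1ccc(C#N)cc1
_SUBSTITUENTS = (
    "C", "CC", "CCC", "CC(C)C", "O", "OC", "OCC", "N", "NC",
    "Cl", "F", "Br", "C#N", "C(=O)O", "C(=O)OC", "C(=O)N",
)

_CHAIN_TAILS = ("O", "N", "Cl", "C(=O)O", "C(=O)OC", "OC", "C#N", "C(=O)N")

#: stereoisomer pairs (same molecule once stereochemistry is stripped)
STEREO_PAIRS = (
    ("C[C@H](N)C(=O)O", "C[C@@H](N)C(=O)O"),          # alanine
    ("C[C@H](O)CC", "C[C@@H](O)CC"),                   # 2-butanol
    ("O[C@H](c1ccccc1)C(=O)O", "O[C@@H](c1ccccc1)C(=O)O"),  # mandelic acid
    ("C[C@H](N)c1ccccc1", "C[C@@H](N)c1ccccc1"),       # 1-phenylethylamine
)


def fixture_smiles() -> list[str]:
    """~200 valid SMILES: chains, substituted benzenes, stereo variants."""
    out = []
    for k in range(1, 13):
        for tail in _CHAIN_TAILS:
            out.append("C" * k + tail)
    for frag in _PREFIXES:
        out.append(f"{frag}c1ccccc1")
    for i, a in enumerate(_PREFIXES):
        for b in _SUBSTITUENTS[i:]:
            out.append(f"{a}c1ccc({b})cc1")
    for a, b in STEREO_PAIRS:
        out.extend((a, b))
    return out


@lru_cache(maxsize=1)
def distinct_canonical_smiles() -> list[str]:
    """Fixture SMILES deduplicated by non-stereospecific canonical form,
    in deterministic order (first representative of each structure)."""
    from .features import canonicalize_structure

    seen, out = set(), []
    for smi in fixture_smiles():
        canon = canonicalize_structure(smi)
        if canon not in seen:
            seen.add(canon)
            out.append(smi)
    return out
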