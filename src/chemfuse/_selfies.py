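"""A compact encoder from SMILES to SELFIES-style token sequences.

SELFIES (self-referencing embedded strings) is a molecular string grammar
in which every symbol sequence decodes to a valid molecule.  This module
implements the *encoding* direction only — turning a molecule into a
deterministic token sequence — which is all the similarity model needs:
downstream the sequence is reduced to a bag-of-tokens count vector, so
what matters is that chemically identical molecules yield identical
sequences and that the token inventory is stable.

The encoding follows the standard derivation from a kekulized canonical
SMILES: atom symbols become bracketed tokens with any incoming bond order
prefixed (``[C]``, ``[=O]``, ``[#N]``), branches become ``[BranchL]``
symbols followed by base-16 index tokens giving the branch length, and
ring closures become ``[RingL]`` symbols followed by index tokens giving
the ring span.  Stereochemistry is dropped before encoding.
"""

from __future__ import annotations

import re

from rdkit import Chem

__all__ = ["smiles_to_selfies_tokens", "SelfiesEncodingError"]

# The 16 symbols used to spell non-negative integers in base 16, in the
# conventional SELFIES index-alphabet order.
_INDEX_ALPHABET = [
    "[C]", "[Ring1]", "[Ring2]",
    "[Branch1]", "[=Branch1]", "[#Branch1]",
    "[Branch2]", "[=Branch2]", "[#Branch2]",
    "[Branch3]", "[=Branch3]", "[#Branch3]",
    "[O]", "[N]", "[=N]", "[=C]",
]

_SMILES_TOKEN_RE = re.compile(
    r"(\[[^\]]+\]|Br|Cl|B|C|N|O|P|S|F|I|b|c|n|o|p|s|@|=|#|-|/|\\|\(|\)|%\d{2}|\d|\.)"
)

_BOND_PREFIX = {"": "", "-": "", "=": "=", "#": "#", "/": "", "\\": ""}


class SelfiesEncodingError(ValueError):
    """The molecule could not be converted to a token sequence."""


def _index_tokens(q: int) -> list[str]:
    """Spell the non-negative integer ``q`` in base 16 index symbols."""
    if q == 0:
        return [_INDEX_ALPHABET[0]]
    digits: list[int] = []
    while q > 0:
        digits.append(q % 16)
        q //= 16
    return [_INDEX_ALPHABET[d] for d in reversed(digits)]


class _Encoder:
    def __init__(self, smiles_tokens: list[str]):
        self.toks = smiles_tokens
        self.pos = 0
        self.atom_count = 0          # atoms emitted so far, globally
        self.ring_open: dict[str, tuple[int, str]] = {}  # ring id -> (atom index, bond)

    def encode(self) -> list[str]:
        out = self._sequence(stop_at_close=False)
        if self.pos != len(self.toks):
            raise SelfiesEncodingError("unbalanced branch parentheses")
        return out

    def _sequence(self, stop_at_close: bool) -> list[str]:
        out: list[str] = []
        bond = ""
        while self.pos < len(self.toks):
            tok = self.toks[self.pos]
            if tok == ")":
                if not stop_at_close:
                    raise SelfiesEncodingError("unexpected ')'")
                return out
            self.pos += 1
            if tok == ".":
                raise SelfiesEncodingError("disconnected structures are not encodable")
            if tok in ("=", "#", "-", "/", "\\"):
                bond = tok
            elif tok == "(":
                inner = self._sequence(stop_at_close=True)
                if self.pos >= len(self.toks) or self.toks[self.pos] != ")":
                    raise SelfiesEncodingError("unbalanced branch parentheses")
                self.pos += 1
                idx = _index_tokens(len(inner) - 1)
                out.append(f"[Branch{len(idx)}]")
                out.extend(idx)
                out.extend(inner)
            elif tok[0].isdigit() or tok[0] == "%":
                ring_id = tok.lstrip("%")
                if ring_id in self.ring_open:
                    open_atom, open_bond = self.ring_open.pop(ring_id)
                    span = self.atom_count - open_atom - 1
                    if span < 0:
                        raise SelfiesEncodingError("ring closure before ring opening atom")
                    idx = _index_tokens(span)
                    prefix = _BOND_PREFIX.get(bond or open_bond, "")
                    out.append(f"[{prefix}Ring{len(idx)}]")
                    out.extend(idx)
                else:
                    self.ring_open[ring_id] = (self.atom_count - 1, bond)
                bond = ""
            elif tok == "@":
                continue  # stereo markers are dropped
            else:  # an atom token
                out.append(self._atom_token(tok, bond))
                self.atom_count += 1
                bond = ""
        return out

    @staticmethod
    def _atom_token(tok: str, bond: str) -> str:
        prefix = _BOND_PREFIX.get(bond, "")
        body = tok[1:-1] if tok.startswith("[") else tok
        body = body.replace("@@", "").replace("@", "")
        return f"[{prefix}{body}]"


def smiles_to_selfies_tokens(smiles: str) -> list[str]:
    """Encode a SMILES string into a SELFIES-style token list.

    Raises :class:`SelfiesEncodingError` for unparsable or disconnected
    input.  The output is deterministic for chemically identical
    molecules because encoding starts from the kekulized canonical
    SMILES.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SelfiesEncodingError(f"unparsable SMILES: {smiles!r}")
    Chem.RemoveStereochemistry(mol)
    try:
        kek = Chem.MolToSmiles(mol, kekuleSmiles=True, canonical=True, isomericSmiles=False)
    except Exception as exc:  # pragma: no cover - kekulization failure is rare
        raise SelfiesEncodingError(f"kekulization failed for {smiles!r}") from exc
    pieces = _SMILES_TOKEN_RE.findall(kek)
    if "".join(pieces) != kek:
        raise SelfiesEncodingError(f"untokenizable SMILES output: {kek!r}")
    return _Encoder(pieces).encode()
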