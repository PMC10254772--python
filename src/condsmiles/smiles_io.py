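"""SMILES tokenization, vocabulary handling, canonicalization and table I/O.

Tokenization is regex-based and exactly reversible: bracket atoms
(``[nH]``, ``[O-]``), the two-letter halogens ``Cl``/``Br``, ``%NN`` ring
closures and all single-character SMILES symbols each become one token, so
that concatenating the tokens reproduces the input string. Canonicalization
goes through RDKit; an unparseable string yields the ``INVALID`` marker
rather than an exception, because invalidity is data for a generative
model, not an error.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")  # parse failures are expected data, keep stderr clean

# Special tokens framing model inputs. PAD=0 so padding masks are index-testable.
PAD, BOS, EOS = "<pad>", "<bos>", "<eos>"
PAD_IDX, BOS_IDX, EOS_IDX = 0, 1, 2
SPECIALS = (PAD, BOS, EOS)

#: Marker returned by :func:`canonicalize` for unparseable SMILES.
INVALID = ""

_TOKEN_RE = re.compile(
    r"(\[[^\]]+\]"          # bracket atoms, e.g. [nH], [O-], [C@@H]
    r"|%\d{2}"              # two-digit ring closures
    r"|Cl|Br"               # two-letter elements
    r"|[BCNOSPFIbcnosp]"    # organic-subset atoms
    r"|[0-9]"               # ring-bond digits
    r"|[=#\-\+\(\)/\\\.@:~\*\$])"  # bonds, branches, stereo, misc
)


class TokenizationError(ValueError):
    """Raised when a SMILES string contains an unsupported character."""

    def __init__(self, smiles: str, position: int):
        self.position = position
        super().__init__(
            f"cannot tokenize {smiles!r}: unsupported character "
            f"{smiles[position]!r} at position {position}"
        )


def tokenize_smiles(smiles: str) -> list[str]:
    """Split a SMILES string into reversible tokens.

    Raises :class:`TokenizationError` naming the offending position if a
    character outside the supported alphabet is met.
    """
    if not smiles:
        raise ValueError("cannot tokenize an empty SMILES string")
    tokens: list[str] = []
    pos = 0
    while pos < len(smiles):
        m = _TOKEN_RE.match(smiles, pos)
        if m is None:
            raise TokenizationError(smiles, pos)
        tokens.append(m.group(0))
        pos = m.end()
    return tokens


def detokenize(tokens: Sequence[str]) -> str:
    """Concatenate tokens back into a SMILES string, dropping BOS/EOS/PAD."""
    return "".join(t for t in tokens if t not in SPECIALS)


@dataclass(frozen=True)
class Vocabulary:
    """Bijection between tokens and contiguous non-negative integers.

    Specials occupy fixed slots (PAD=0, BOS=1, EOS=2); corpus tokens follow
    in lexicographic order, so the mapping is a deterministic function of
    the token *set* of the corpus.
    """

    token_to_index: dict[str, int]
    index_to_token: tuple[str, ...] = field(init=False, repr=False)

    def __post_init__(self):
        inv = sorted(self.token_to_index, key=self.token_to_index.get)
        object.__setattr__(self, "index_to_token", tuple(inv))
        if [self.token_to_index[t] for t in inv] != list(range(len(inv))):
            raise ValueError("token indices must be contiguous from 0")

    def __len__(self) -> int:
        return len(self.token_to_index)

    def __contains__(self, token: str) -> bool:
        return token in self.token_to_index

    def encode(self, tokens: Sequence[str], add_specials: bool = True) -> list[int]:
        try:
            body = [self.token_to_index[t] for t in tokens]
        except KeyError as e:
            raise KeyError(f"token {e.args[0]!r} not in vocabulary") from None
        return [BOS_IDX] + body + [EOS_IDX] if add_specials else body

    def decode(self, indices: Iterable[int]) -> list[str]:
        return [self.index_to_token[i] for i in indices]

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.token_to_index, indent=0))

    @classmethod
    def from_json(cls, path) -> "Vocabulary":
        return cls(json.loads(Path(path).read_text()))


def build_vocabulary(corpus: Iterable[str]) -> Vocabulary:
    """Build a :class:`Vocabulary` from an iterable of SMILES strings."""
    seen: set[str] = set()
    n = 0
    for s in corpus:
        seen.update(tokenize_smiles(s))
        n += 1
    if n == 0:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    mapping = {PAD: PAD_IDX, BOS: BOS_IDX, EOS: EOS_IDX}
    for i, tok in enumerate(sorted(seen)):
        mapping[tok] = len(SPECIALS) + i
    return Vocabulary(mapping)


def canonicalize(smiles: str) -> str:
    """Return the RDKit-canonical SMILES, or :data:`INVALID` if unparseable."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return INVALID
    return Chem.MolToSmiles(mol)


def is_valid(smiles: str) -> bool:
    return canonicalize(smiles) != INVALID


@dataclass
class MoleculeRecord:
    """One molecule with optional condition label and activity."""

    smiles: str
    canonical: Optional[str] = None
    target_id: Optional[str] = None
    pxc50: Optional[float] = None


def read_molecule_table(path, fmt: Optional[str] = None) -> list[MoleculeRecord]:
    """Read a ``.smi`` file or a CSV with columns smiles[,target_id][,pxc50].

    ``fmt`` is inferred from the extension when omitted. Row order is
    preserved; blank lines are skipped.
    """
    path = Path(path)
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "smi"
    if fmt == "smi":
        records = []
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line:
                continue
            records.append(MoleculeRecord(smiles=line.split()[0]))
        return records
    if fmt == "csv":
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or "smiles" not in reader.fieldnames:
                raise ValueError(f"{path}: CSV must have a 'smiles' header column")
            records = []
            for row in reader:
                if not (row.get("smiles") or "").strip():
                    continue
                pxc = row.get("pxc50")
                records.append(MoleculeRecord(
                    smiles=row["smiles"].strip(),
                    target_id=(row.get("target_id") or "").strip() or None,
                    pxc50=float(pxc) if pxc not in (None, "") else None,
                ))
            return records
    raise ValueError(f"unknown format {fmt!r} (expected 'smi' or 'csv')")


def write_molecule_table(path, records: Sequence[MoleculeRecord]) -> None:
    """Write records as .smi (smiles only) or CSV depending on extension."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        has_act = any(r.pxc50 is not None for r in records)
        with path.open("w", newline="", encoding="utf-8") as fh:
            cols = ["smiles", "target_id"] + (["pxc50"] if has_act else [])
            w = csv.writer(fh)
            w.writerow(cols)
            for r in records:
                row = [r.smiles, r.target_id or ""]
                if has_act:
                    row.append("" if r.pxc50 is None else f"{r.pxc50:.6g}")
                w.writerow(row)
    else:
        path.write_text("".join(r.smiles + "\n" for r in records))
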