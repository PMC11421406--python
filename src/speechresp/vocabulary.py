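"""The 50-word matrix vocabulary of a matrix sentence test.

Matrix tests (e.g., the German OLSA) build five-word sentences with the
fixed syntactic structure name–verb–number–adjective–object.  Each of the
five slots has ten interchangeable words, so every test sentence is one
path through a 5x10 word matrix.  Response words outside the matrix are
represented by the literal out-of-vocabulary marker ``<OOV>``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

OOV = "<OOV>"

SLOT_NAMES = ("name", "verb", "number", "adjective", "object")

# The published German OLSA base matrix (10 words per slot).
_OLSA_MATRIX = (
    ("Peter", "Kerstin", "Tanja", "Ulrich", "Britta",
     "Wolfgang", "Nina", "Stefan", "Thomas", "Doris"),
    ("bekommt", "sieht", "gibt", "hat", "gewann",
     "kauft", "malt", "nahm", "schenkt", "verleiht"),
    ("zwei", "drei", "vier", "fünf", "sieben",
     "acht", "neun", "elf", "zwölf", "achtzehn"),
    ("alte", "graue", "grüne", "kleine", "große",
     "nasse", "rote", "schöne", "teure", "weiße"),
    ("Autos", "Bilder", "Blumen", "Dosen", "Messer",
     "Ringe", "Schuhe", "Sessel", "Steine", "Tassen"),
)


@dataclass(frozen=True)
class Vocabulary:
    """A 5-slot x 10-word matrix vocabulary.

    Invariants: 50 unique words, each word in exactly one slot.
    """

    matrix: tuple = _OLSA_MATRIX
    _slot_of: dict = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self):
        if len(self.matrix) != 5 or any(len(s) != 10 for s in self.matrix):
            raise ValueError("matrix must have 5 slots of 10 words each")
        slot_of = {}
        for i, slot in enumerate(self.matrix):
            for w in slot:
                if w in slot_of:
                    raise ValueError(f"word {w!r} appears in more than one slot")
                slot_of[w] = i
        object.__setattr__(self, "_slot_of", slot_of)

    @property
    def words(self) -> frozenset:
        return frozenset(self._slot_of)

    def __contains__(self, word: str) -> bool:
        return word in self._slot_of

    def slot_of(self, word: str) -> int:
        """Index (0-4) of the slot a matrix word belongs to."""
        try:
            return self._slot_of[word]
        except KeyError:
            raise KeyError(f"{word!r} is not in the matrix vocabulary") from None

    def canonical(self, token: str) -> str:
        """Map an arbitrary response token into the vocabulary, else <OOV>."""
        return token if token in self._slot_of or token == OOV else OOV


DEFAULT_VOCABULARY = Vocabulary()
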