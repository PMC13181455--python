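"""Exception hierarchy for protacdec."""


class ProtacDecError(Exception):
    """Base class for all protacdec errors."""


class InputError(ProtacDecError):
    """Malformed user input (empty SMILES, bad CSV schema, mismatched labels...)."""


class SmilesParseError(InputError):
    """A SMILES string could not be parsed into a molecule."""

    def __init__(self, smiles: str, detail: str = ""):
        self.smiles = smiles
        msg = f"unparseable SMILES: {smiles!r}"
        if detail:
            msg += f" ({detail})"
        super().__init__(msg)


class LibraryError(ProtacDecError):
    """A fragment library could not be loaded or is empty."""


class AssemblyError(ProtacDecError):
    """A synthetic PROTAC could not be assembled at the requested sites."""


class DegenerateSubtractionError(ProtacDecError):
    """Subtracting a match left no atoms (the fragment covered the whole molecule)."""


class ContractError(ProtacDecError):
    """An internal API contract was violated by the caller."""
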