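"""Exception hierarchy used across the package."""


class AsmbenchError(Exception):
    """Base class for all package errors."""


class InputError(AsmbenchError, ValueError):
    """An argument violates a documented precondition."""


class CapacityError(AsmbenchError, ValueError):
    """A request cannot be satisfied within the genome/feature budget."""


class ConsistencyError(AsmbenchError, ValueError):
    """Inputs that must agree (e.g. variant REF vs reference base) do not."""
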