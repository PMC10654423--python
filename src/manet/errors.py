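"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """An architecture or preprocessing option is invalid (e.g. odd width)."""


class ShapeContractError(ValueError):
    """Feature-map extents violate an operator's shape contract."""


class GenerationError(RuntimeError):
    """The phantom generator could not satisfy its spec (e.g. tumors don't fit)."""
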