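"""Exception hierarchy shared across the toolchain.

Exit-code mapping used by the command line interface:
configuration problems -> 2, numerical/meshing failures -> 3.
"""


class OrganoidError(Exception):
    """Base class for all toolchain errors."""


class InvalidConfigurationError(OrganoidError):
    """A run configuration or parameter set violates its invariants."""


class TessellationDegeneracyError(OrganoidError):
    """Seed set or triangulation is degenerate (coplanar seeds, huge circumradius...)."""


class TopologyError(OrganoidError):
    """A mesh does not satisfy a required topological property (open surface...)."""


class MeshingError(OrganoidError):
    """FEM discretization failed (inverted element, inconsistent boundary...)."""


class SolverError(OrganoidError):
    """The built-in elasticity solver could not produce a valid solution."""


class DeckError(OrganoidError):
    """Input-deck generation or parsing failed."""
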