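"""Exception hierarchy.

Every error raised on a user-facing path derives from :class:`CoregError`
and carries an ``exit_code`` so the command-line layer can translate
failures into conventional process exit statuses:

* 2 — malformed or inconsistent input (files, tables, geometry)
* 3 — registration failure (ICP could not retain enough correspondences)
* 4 — marker extraction / correspondence ambiguity
"""

from __future__ import annotations


class CoregError(Exception):
    """Base class for all toolbox errors."""

    exit_code = 1


class InputError(CoregError):
    """Invalid argument values or inconsistent inputs."""

    exit_code = 2


class FormatError(InputError):
    """A file could not be parsed in its declared format."""


class FrameError(InputError):
    """Data expressed in one coordinate frame used where another was expected."""


class DegenerateGeometryError(InputError):
    """Point configuration too degenerate (collinear/coincident) to define a fit."""


class RegistrationError(CoregError):
    """Surface registration failed (e.g. too few valid correspondences)."""

    exit_code = 3


class MarkerCountError(CoregError):
    """Detected marker count differs from the expected count."""

    exit_code = 4


class AmbiguityError(CoregError):
    """Marker correspondence is ambiguous (near-symmetric configuration)."""

    exit_code = 4
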