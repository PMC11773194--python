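"""Exception hierarchy.

Every exception carries a stable machine-readable ``code`` so that callers
(and the CLI) can branch on failure class without parsing messages.
"""

from __future__ import annotations


class InstanceMapError(Exception):
    """Base class for all package errors."""

    code: str = "E_INSTANCEMAP"


class UnknownKindError(InstanceMapError):
    code = "E_UNKNOWN_KIND"


class UnknownLegacyTermError(InstanceMapError):
    code = "E_UNKNOWN_LEGACY_TERM"


class DuplicateNodeError(InstanceMapError):
    code = "E_DUP_NODE"


class DuplicateEdgeError(InstanceMapError):
    code = "E_DUP_EDGE"


class DanglingReferenceError(InstanceMapError):
    code = "E_DANGLING"


class BadIdError(InstanceMapError):
    code = "E_BAD_ID"


class CyclicMapError(InstanceMapError):
    code = "E_CYCLIC"


class FormatVersionError(InstanceMapError):
    code = "E_FORMAT_VERSION"


class SchemaError(InstanceMapError):
    """Document does not conform to the map schema.

    ``location`` is a JSON-pointer-style path into the offending document,
    e.g. ``/edges/3/target``.
    """

    code = "E_SCHEMA"

    def __init__(self, message: str, location: str = "") -> None:
        super().__init__(f"{location}: {message}" if location else message)
        self.location = location


class FormatError(InstanceMapError):
    code = "E_FORMAT"


class OrphanSupplementaryError(InstanceMapError):
    code = "E_ORPHAN_SUPPLEMENTARY"


class IdCollisionError(InstanceMapError):
    code = "E_ID_COLLISION"


class UnknownFixtureError(InstanceMapError):
    code = "E_UNKNOWN_FIXTURE"
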