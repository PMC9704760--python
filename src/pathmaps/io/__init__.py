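"""Readers and writers for the supported pathway-map formats.

Every reader returns a :class:`ParseReport` wrapping a
:class:`~pathmaps.core.PathwayGraph` plus a list of warnings for
constructs that were skipped or defaulted; unknown glyph/arc classes
degrade to ``generic`` rather than failing the parse.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import List

from ..core import PathwayGraph

__all__ = [
    "SourceFormat",
    "ParseReport",
    "ParseError",
    "read",
    "read_sbgnml",
    "read_sbml",
    "read_graphml",
    "read_json",
    "write_elements_json",
    "write_layout_json",
]


class ParseError(ValueError):
    """Malformed input document."""


class SourceFormat(str, Enum):
    SBGNML = "sbgnml"
    SBML = "sbml"
    GRAPHML = "graphml"
    JSON = "json"


@dataclass
class ParseReport:
    graph: PathwayGraph
    warnings: List[str] = field(default_factory=list)
    source_format: SourceFormat = SourceFormat.JSON


from .sbgnml import read_sbgnml  # noqa: E402
from .sbml import read_sbml  # noqa: E402
from .graphml import read_graphml  # noqa: E402
from .elements import read_json, write_elements_json, write_layout_json  # noqa: E402

_READERS = {
    SourceFormat.SBGNML: read_sbgnml,
    SourceFormat.SBML: read_sbml,
    SourceFormat.GRAPHML: read_graphml,
    SourceFormat.JSON: read_json,
}


def read(text: str, fmt: "SourceFormat | str") -> ParseReport:
    """Parse ``text`` in the given format."""
    return _READERS[SourceFormat(fmt)](text)
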