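"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: :class:`ValidationError` -> 2,
:class:`ConfigurationError` -> 3.
"""


class GazeDialogueError(Exception):
    """Base class for all package errors."""


class ValidationError(GazeDialogueError, ValueError):
    """Malformed or inconsistent input data (bad keypoints, bad intervals,
    mismatched timelines, empty streams)."""


class AlignmentError(ValidationError):
    """Two windowed series do not share a common grid (window length or
    start time differ) and cannot be combined without resampling."""


class ConfigurationError(GazeDialogueError, ValueError):
    """Invalid or unusable configuration (unknown backend, bad index map)."""
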