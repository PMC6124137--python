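"""Exception hierarchy shared by all fightkit modules."""


class FightkitError(Exception):
    """Base class for all fightkit errors."""


class ConfigError(FightkitError, ValueError):
    """Invalid configuration value."""


class FormatError(FightkitError):
    """Input file does not match the expected schema."""


class GapError(FormatError):
    """Frame index is not contiguous."""

    def __init__(self, missing_frames):
        self.missing_frames = list(missing_frames)
        shown = ", ".join(str(f) for f in self.missing_frames[:10])
        more = "" if len(self.missing_frames) <= 10 else ", ..."
        super().__init__(f"missing frames: {shown}{more}")


class BoundsError(FightkitError):
    """Position lies outside the arena."""


class InsufficientDataError(FightkitError):
    """Too few samples for the requested operation."""


class ConvergenceError(FightkitError):
    """Iterative fit failed to converge."""


class SamplingError(FightkitError):
    """Requested sample cannot be drawn from the available data."""


class TrainingError(FightkitError):
    """Classifier training is impossible on the given data."""


class WindowError(FightkitError):
    """Requested frame lies before the first complete feature window."""


class DegenerateFrameError(FightkitError):
    """Geometric frame is undefined (coincident fish or zero heading)."""


class UndefinedCorrelationError(FightkitError):
    """Correlation undefined (zero variance input)."""


class CollinearityError(FightkitError):
    """Design matrix is rank deficient."""


class EmptyResultError(FightkitError):
    """No data remain after filtering/exclusion."""
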