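"""The nine-test neuropsychological battery and its metadata.

Each test is described by a :class:`TestSpec`: which direction means "better",
the legal score range, whether an alternate form is used at retest, and whether
the test contributes to the six-test composite practice effect.  The two
Trail Making tests (completion times) are the only measures where a *lower*
score is better; their SRB z-scores are sign-reversed downstream so positive
always means more improvement than expected.

The composite members are the Letter-Number Sequencing Test, Symbol Digit
Modalities Test, Semantic Fluency Test, Judgment of Line Orientation, and the
HVLT-R immediate and delayed recall trials.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple


@dataclass(frozen=True)
class TestSpec:
    """Metadata for one battery test.

    Parameters
    ----------
    name : str
        Canonical short identifier, also the column name in visit tables.
    label : str
        Human-readable name.
    direction : {"higher_is_better", "lower_is_better"}
        Orientation of the raw score.
    score_range : tuple
        (min, max); ``max`` is ``None`` for unbounded-above measures
        (semantic fluency counts, Trail Making completion times).
    alternate_form : bool
        Whether a parallel test form is used at retest.
    composite_member : bool
        Whether the test enters the six-test composite practice effect.
    """

    name: str
    label: str
    direction: str
    score_range: Tuple[float, Optional[float]]
    alternate_form: bool = False
    composite_member: bool = False

    @property
    def sign(self) -> int:
        """+1 if higher raw scores are better, -1 otherwise."""
        return -1 if self.direction == "lower_is_better" else 1


BATTERY: dict[str, TestSpec] = {
    t.name: t
    for t in [
        TestSpec("lnst", "Letter-Number Sequencing Test", "higher_is_better",
                 (0, 21), composite_member=True),
        TestSpec("bnt", "Boston Naming Test", "higher_is_better", (0, 60)),
        TestSpec("sdmt", "Symbol Digit Modalities Test", "higher_is_better",
                 (0, 110), alternate_form=True, composite_member=True),
        TestSpec("sft", "Semantic Fluency Test", "higher_is_better",
                 (0, None), composite_member=True),
        TestSpec("jolo", "Judgment of Line Orientation", "higher_is_better",
                 (0, 15), alternate_form=True, composite_member=True),
        TestSpec("tmt_a", "Trail Making Test A", "lower_is_better", (0, None)),
        TestSpec("tmt_b", "Trail Making Test B", "lower_is_better", (0, None)),
        TestSpec("hvlt_imm", "HVLT-R immediate recall", "higher_is_better",
                 (0, 36), alternate_form=True, composite_member=True),
        TestSpec("hvlt_del", "HVLT-R delayed recall", "higher_is_better",
                 (0, 12), alternate_form=True, composite_member=True),
    ]
}

TEST_NAMES: tuple[str, ...] = tuple(BATTERY)
COMPOSITE_MEMBERS: tuple[str, ...] = tuple(
    t.name for t in BATTERY.values() if t.composite_member
)

assert len(COMPOSITE_MEMBERS) == 6
assert tuple(t.name for t in BATTERY.values() if t.direction == "lower_is_better") == (
    "tmt_a", "tmt_b",
)


def get_test(name: str) -> TestSpec:
    """Return the :class:`TestSpec` for ``name``, raising ``KeyError`` with a
    helpful message for unknown tests."""
    try:
        return BATTERY[name]
    except KeyError:
        raise KeyError(
            f"unknown battery test {name!r}; known tests: {', '.join(TEST_NAMES)}"
        ) from None
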