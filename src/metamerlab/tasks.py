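"""Constants of the reference recognition tasks.

The visual task is a 16-way choice among entry-level object categories; the
auditory task asks for the word at the center of a speech excerpt, chosen
from a 793-entry response vocabulary (models additionally carry a 'null'
class, giving 794 output labels).
"""

IMAGE_CATEGORIES_16 = [
    "airplane", "bear", "bicycle", "bird", "boat", "bottle", "car", "cat",
    "chair", "clock", "dog", "elephant", "keyboard", "knife", "oven", "truck",
]

WORD_VOCAB_SIZE = 793          # response choices in the behavioral task
WORD_VOCAB_SIZE_WITH_NULL = 794  # model output labels, including 'null'


def chance_level(n_choices: int) -> float:
    """Accuracy of uniform guessing on an n-way task."""
    if n_choices < 1:
        raise ValueError("need at least one choice")
    return 1.0 / n_choices
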