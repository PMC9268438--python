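"""The published worked example: origin-assignment tables as printed.

Feeds the packaged (actual, recognized) pairs of the 31 training
batches (raw vs Z-scored input) and the 8 market test batches through
the truncated-percent accuracy rule and prints the side-by-side
report.
"""

from ginsengms import (
    accuracy_from_pairs,
    load_published_test_pairs,
    load_published_training_pairs,
)
from ginsengms.pipeline import make_report

train = load_published_training_pairs()
test = load_published_test_pairs()

raw = list(zip(train.actual, train.recognized_raw))
norm = list(zip(train.actual, train.recognized_normalized))
tp = list(zip(test.actual, test.recognized))

print(make_report(raw, norm, tp))
print()
print(
    f"raw {accuracy_from_pairs(raw)}%  "
    f"(26/31 correct truncates to 83, not rounds to 84); "
    f"normalized {accuracy_from_pairs(norm)}%; test {accuracy_from_pairs(tp)}%"
)
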