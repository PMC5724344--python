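"""Score usability questionnaires: SUS (10 items, 1-5) and USE (30 items, 1-7).

SUS: odd items are positively phrased (contribute response−1), even items
negatively phrased (contribute 5−response); the sum is scaled by 2.5 onto
0–100. USE items may be marked not-applicable; medians are taken over the
answered items, per respondent and per dimension.
"""

from ctsearch import SUSResponse, USEResponse, sus_score, use_summary

for label, items in [
    ("mixed response", (4, 1, 4, 2, 4, 2, 4, 2, 4, 2)),
    ("most favorable", (5, 1, 5, 1, 5, 1, 5, 1, 5, 1)),
    ("all neutral   ", (3,) * 10),
]:
    print(f"SUS {label}: {sus_score(SUSResponse('r', items)):5.1f} / 100")

use = USEResponse(
    "radiologist-1",
    items=tuple([6] * 8          # usefulness
                + [6] * 11       # ease of use
                + [7] * 4        # ease of learning
                + [6, 6, 5] + [None] * 4),  # satisfaction, 4 items N/A
)
summary = use_summary([use])
print("\nUSE per-dimension medians:", summary["per_dimension_median"])
print("USE overall median:", summary["overall_median"],
      "(on the 1-7 agreement scale; N/A items excluded)")
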