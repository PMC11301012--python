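"""Tabulate treatment-status questionnaires and test care-seeking change.

Uses the published pre/post counts for notified participants, then shows
McNemar's test on an illustrative paired dichotomy (regular treatment vs
the other four behaviors).
"""

from hbpnotify import mcnemar_counts, tabulate_counts
from hbpnotify.behavior import ANSWER_CATEGORIES

pre = tabulate_counts([95, 15, 39, 24, 55], "pre", n_no_answer=26)
post = tabulate_counts([116, 3, 21, 8, 15], "post", n_no_answer=91)

print(f"{'answer':<26}{'pre':>12}{'post':>12}")
for cat in ANSWER_CATEGORIES:
    print(
        f"{cat:<26}{pre.counts[cat]:>5} ({pre.percentages[cat]:4.1f}%)"
        f"{post.counts[cat]:>5} ({post.percentages[cat]:4.1f}%)"
    )

m = mcnemar_counts(b=5, c=15)
print(
    f"\nMcNemar on b=5 regular->other vs c=15 other->regular discordant pairs: "
    f"statistic {m.statistic:.2f}, chi-squared p {m.p_value:.3f}, "
    f"exact binomial p {m.exact_p:.3f}"
)
print(
    "Regular treatment rose from 41.7% of pre-survey respondents to 71.2% "
    "after notification; the McNemar statistic tests whether switches toward "
    "regular treatment outnumber switches away."
)
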