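"""Help/harm compatibility on a tiny hand-built example.

Compatibility compares a system ranking against an ideal ranking with
truncated, normalized rank-biased overlap: top-weighted, so getting the
first few documents right matters far more than the tail.
"""

from qualrank import (
    Judgment,
    JudgmentSet,
    Ranking,
    Topic,
    compatibility,
    derive_preference_labels,
    help_harm_report,
    ideal_ranking,
)

# One topic about an effective treatment ("helpful" stance).
topics = [Topic("t1", "honey cough children", stance="helpful")]

# Judged documents: two support the treatment (helpful), one dissuades
# from it (harmful for a helpful topic), one is off-topic.
js = JudgmentSet()
js.add(Judgment("t1", "d_good1", usefulness=2, supportiveness="supportive", credibility=1))
js.add(Judgment("t1", "d_good2", usefulness=1, supportiveness="supportive", credibility=0))
js.add(Judgment("t1", "d_bad", usefulness=2, supportiveness="dissuasive", credibility=0))
js.add(Judgment("t1", "d_offtopic", usefulness=0, supportiveness="neutral", credibility=0))
qrels = derive_preference_labels(js, topics)

run = Ranking("t1", [("d_good1", 4.0), ("d_bad", 3.0), ("d_good2", 2.0), ("d_offtopic", 1.0)])

i_help = ideal_ranking(qrels, "t1", "helpful")
i_harm = ideal_ranking(qrels, "t1", "harmful")
print(f"ideal helpful ranking: {i_help.doc_ids}")
print(f"ideal harmful ranking: {i_harm.doc_ids}")

help_c = compatibility(run, i_help)
harm_c = compatibility(run, i_harm)
print(f"help compatibility  = {help_c:.3f}  (how early the helpful docs appear)")
print(f"harm compatibility  = {harm_c:.3f}  (how early the harmful doc appears)")
print(f"help - harm         = {help_c - harm_c:.3f}  (positive: net helpful ranking)")

report = help_harm_report([run], qrels, topics)
print(f"report agrees: help-harm(all_T) = {report.mean('help_harm'):.3f}")
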