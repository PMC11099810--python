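"""Page credibility from cheap surface features plus a trusted-domain list.

Credibility is estimated from readability (SMOG grade), page-design effort
(CSS rule count) and an importance proxy, fed to a small classifier; pages
from a curated trusted-domain list get a decisive +1 bonus so they always
outrank untrusted pages.
"""

import numpy as np

from qualrank import (
    CredibilityFeatures,
    Document,
    TrustedDomainList,
    count_css_rules,
    credibility_score,
    smog_index,
    train_credibility_classifier,
)

simple = "The cat sat on the mat. The dog ran to the park. It was a good day."
dense = ("Epidemiological investigations demonstrate considerable heterogeneity. "
         "Pharmacological interventions necessitate individualized consideration.")
print(f"SMOG grade, plain text:   {smog_index(simple):.2f}")
print(f"SMOG grade, medical text: {smog_index(dense):.2f}  (more schooling needed)")

html = ('<html><head><style>p { color: #222; } h1 { margin: 0; }</style></head>'
        '<body><div style="padding:4px">content</div></body></html>')
print(f"CSS rules counted in the sample page: {count_css_rules(html)}")

# Train a toy classifier: credible pages here are the better-designed ones.
rng = np.random.default_rng(0)
feats, labels = [], []
for i in range(80):
    credible = i % 2
    feats.append(CredibilityFeatures(
        smog=rng.normal(9 + 2 * credible, 0.5),
        css_rule_count=int(rng.integers(0, 10) + 15 * credible),
        page_rank=float(rng.random()),
    ))
    labels.append(credible)
clf = train_credibility_classifier(feats, labels, seed=0)

trusted = TrustedDomainList(["hon.ch", "nih.gov"])
doc_trusted = Document("a", dense, url="https://medlineplus.nih.gov/cough")
doc_unknown = Document("b", dense, url="https://miracle-cures.example.com/cough")
s_t = credibility_score(doc_trusted, clf, trusted)
s_u = credibility_score(doc_unknown, clf, trusted)
print(f"score for nih.gov page:   {s_t:.3f}  (classifier probability + 1.0 bonus)")
print(f"score for unknown domain: {s_u:.3f}  (probability alone, always < trusted)")
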