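# Gastrointestinal adverse-event Preferred Terms (MedDRA-style).
# Primarily PTs under the System Organ Class "Gastrointestinal disorders",
# plus oral/digestive-tract terms commonly reported with smoking-cessation
# medications (dry mouth, hiccups, dental caries, decreased appetite,
# anorexia).  One term per line; matching is case-insensitive; replace this
# file to use a licensed or extended PT list.
Nausea
Vomiting
Diarrhoea
Constipation
Abdominal pain
Abdominal pain upper
Abdominal pain lower
Abdominal discomfort
Abdominal distension
Dyspepsia
Flatulence
Eructation
Haematochezia
Gastrooesophageal reflux disease
Gastric ulcer
Gastritis
Gastric disorder
Mouth ulceration
Stomatitis
Contact stomatitis
Gingivitis
Gingival pain
Glossodynia
Salivary hypersecretion
Dysphagia
Toothache
Dental caries
Dry mouth
Hiccups
Decreased appetite
Anorexia
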