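scale	range_kind	keyword	wave	expected
ordinal	numeric	0	used	NLH
ordinal	numeric	0	unused	PN
ordinal	numeric	1	used	NLH
ordinal	numeric	1	unused	PN
ordinal	pos_neg	0	used	PN
ordinal	pos_neg	0	unused	PN
ordinal	pos_neg	1	used	PN
ordinal	pos_neg	1	unused	PN
ordinal	none	0	used	PN
ordinal	none	0	unused	PN
ordinal	none	1	used	PN
ordinal	none	1	unused	PN
nominal	numeric	0	used	NLH
nominal	numeric	0	unused	UNKNOWN
nominal	numeric	1	used	NLH
nominal	numeric	1	unused	PN
nominal	pos_neg	0	used	PN
nominal	pos_neg	0	unused	UNKNOWN
nominal	pos_neg	1	used	PN
nominal	pos_neg	1	unused	PN
nominal	none	0	used	UNKNOWN
nominal	none	0	unused	UNKNOWN
nominal	none	1	used	PN
nominal	none	1	unused	PN
quantitative	numeric	0	used	NLH
quantitative	numeric	0	unused	NLH
quantitative	numeric	1	used	NLH
quantitative	numeric	1	unused	PN
quantitative	pos_neg	0	used	PN
quantitative	pos_neg	0	unused	NLH
quantitative	pos_neg	1	used	PN
quantitative	pos_neg	1	unused	PN
quantitative	none	0	used	NLH
quantitative	none	0	unused	NLH
quantitative	none	1	used	PN
quantitative	none	1	unused	PN
qualitative	numeric	0	used	NLH
qualitative	numeric	0	unused	UNKNOWN
qualitative	numeric	1	used	NLH
qualitative	numeric	1	unused	PN
qualitative	pos_neg	0	used	PN
qualitative	pos_neg	0	unused	UNKNOWN
qualitative	pos_neg	1	used	PN
qualitative	pos_neg	1	unused	PN
qualitative	none	0	used	UNKNOWN
qualitative	none	0	unused	UNKNOWN
qualitative	none	1	used	PN
qualitative	none	1	unused	PN
narrative	numeric	0	used	NLH
narrative	numeric	0	unused	UNKNOWN
narrative	numeric	1	used	NLH
narrative	numeric	1	unused	PN
narrative	pos_neg	0	used	PN
narrative	pos_neg	0	unused	UNKNOWN
narrative	pos_neg	1	used	PN
narrative	pos_neg	1	unused	PN
narrative	none	0	used	UNKNOWN
narrative	none	0	unused	UNKNOWN
narrative	none	1	used	PN
narrative	none	1	unused	PN
doc	numeric	0	used	NLH
doc	numeric	0	unused	UNKNOWN
doc	numeric	1	used	NLH
doc	numeric	1	unused	PN
doc	pos_neg	0	used	PN
doc	pos_neg	0	unused	UNKNOWN
doc	pos_neg	1	used	PN
doc	pos_neg	1	unused	PN
doc	none	0	used	UNKNOWN
doc	none	0	unused	UNKNOWN
doc	none	1	used	PN
doc	none	1	unused	PN
panel	numeric	0	used	NLH
panel	numeric	0	unused	UNKNOWN
panel	numeric	1	used	NLH
panel	numeric	1	unused	PN
panel	pos_neg	0	used	PN
panel	pos_neg	0	unused	UNKNOWN
panel	pos_neg	1	used	PN
panel	pos_neg	1	unused	PN
panel	none	0	used	UNKNOWN
panel	none	0	unused	UNKNOWN
panel	none	1	used	PN
panel	none	1	unused	PN
unknown	numeric	0	used	NLH
unknown	numeric	0	unused	UNKNOWN
unknown	numeric	1	used	NLH
unknown	numeric	1	unused	PN
unknown	pos_neg	0	used	PN
unknown	pos_neg	0	unused	UNKNOWN
unknown	pos_neg	1	used	PN
unknown	pos_neg	1	unused	PN
unknown	none	0	used	UNKNOWN
unknown	none	0	unused	UNKNOWN
unknown	none	1	used	PN
unknown	none	1	unused	PN
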