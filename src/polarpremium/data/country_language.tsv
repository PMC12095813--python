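# country	language
# Synthetic fixture mapping ISO-3166 alpha-2 country codes to their primary
# language (ISO-639-1).  Illustrative subset only; supply your own
# authoritative table (e.g. derived from GeoNames) for real analyses.
US	en
GB	en
AU	en
FR	fr
BE	fr
DE	de
AT	de
ES	es
MX	es
AR	es
IT	it
PT	pt
BR	pt
NL	nl
FI	fi
JP	ja
VN	vi
MM	my
IN	hi
CN	zh
RU	ru
TR	tr
SA	ar
KR	ko
SE	sv
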