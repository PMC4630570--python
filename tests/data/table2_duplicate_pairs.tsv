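ID1	ID2	Identity (%)
Ii041-AP2	Ii061-AP2	100
Ii042-AP2	Ii061-AP2	100
Ii027-AP2	Ii061-AP2	97.62
Ii061-AP2	Ii042-AP2	95.35
Ii077-AP2	Ii027-AP2	97.73
Ii077-AP2	Ii041-AP2	97.73
Ii076-AP2	Ii077-AP2	98.41
Ii077-AP2	Ii078-AP2	98.41
Ii069-DREB-A6	Ii070-DREB-A6	100
Ii076-AP2	Ii078-AP2	100
Ii061-AP2	Ii062-AP2	100
Ii061-AP2	Ii063-AP2	100
Ii073-DREB-A5	Ii074-DREB-A5	98.88
Ii042-AP2	Ii041-AP2	100
Ii062-AP2	Ii063-AP2	99.62
Ii055-DREB-A2	Ii056-DREB-A2	100
Ii038-AP2	Ii039-AP2	100
Ii016-AP2	Ii017-AP2	98.88
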