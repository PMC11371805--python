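name	aa_start	aa_end
IP	1	20
CAF	152	227
PKD	238	299
RPT	306	510
CS	506	511
KLD	559	609
TM	638	660
cyto	661	713
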