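gene
spo0A
spoIIAA
spoIIAB
spoIIE
spoIIGA
spoIIM
spoIIP
spoIIQ
spoIIR
spoIIID
spoIIIJ
spoIIIAA
spoIIIAB
spoIIIAC
spoIIIAD
spoIIIAE
spoIIIAF
spoIIIAG
spoIIIAH
spoIVA
spoIVB
spoVAC
spoVAD
spoVAE
spoVB
spoVD
spoVE
spoVFA
spoVFB
spoVG
spoVK
spoVS
spoVT
sigE
sigF
sigG
sigH
sigK
sspA
sspB
gpr
sleB
cwlD
dpaA
dpaB
gerAA
gerAB
gerAC
gerD
gerM
cotE
cotJC
yabP
yabQ
ylbJ
ylmC
ymxH
ypeB
yqfC
yqfD
ytaF
ytvI
yunB
yyaC
jag
lonB
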