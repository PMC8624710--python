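acronym,name,M_pair,M_active,chain_length,branched,M_pair_display
[IBU],ibuprofen,206.284,206.284,0,False,206.28
[ValOMe][IBU],L-valine methyl ester ibuprofenate,337.458,206.284,1,False,337.45
[ValOEt][IBU],L-valine ethyl ester ibuprofenate,351.485,206.284,2,False,351.48
[ValOiPr][IBU],L-valine isopropyl ester ibuprofenate,365.512,206.284,3,True,365.51
[ValOPr][IBU],L-valine propyl ester ibuprofenate,365.512,206.284,3,False,365.51
[ValOBu][IBU],L-valine butyl ester ibuprofenate,379.539,206.284,4,False,379.53
[ValOAm][IBU],L-valine amyl ester ibuprofenate,393.565,206.284,5,False,393.56
[ValOHex][IBU],L-valine hexyl ester ibuprofenate,405.576,206.284,6,False,407.59
[ValOHept][IBU],L-valine heptyl ester ibuprofenate,421.619,206.284,7,False,421.61
[ValOOct][IBU],L-valine octyl ester ibuprofenate,435.646,206.284,8,False,435.64
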