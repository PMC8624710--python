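compound,vehicle_mass_g,compound_mass_g,cosolvent_mass_g,total_mass_g
[IBU],0.8501,0.0500,0.1000,1.0001
[ValOMe][IBU],0.8502,0.0820,0.1000,1.0322
[ValOEt][IBU],0.8500,0.0857,0.1000,1.0357
[ValOiPr][IBU],0.8504,0.0890,0.1000,1.0394
[ValOPr][IBU],0.8500,0.0896,0.1000,1.0396
[ValOBu][IBU],0.8501,0.0920,0.1000,1.0421
[ValOAm][IBU],0.8502,0.0954,0.1000,1.0456
[ValOHex][IBU],0.8500,0.0982,0.1000,1.0482
[ValOHept][IBU],0.8504,0.1020,0.1000,1.0524
[ValOOct][IBU],0.8503,0.1060,0.1000,1.0563
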