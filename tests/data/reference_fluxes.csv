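compound,membrane,Jss_mean
[IBU],skin,36.98
[IBU],strat-m,163.45
[ValOMe][IBU],skin,36.37
[ValOMe][IBU],strat-m,82.38
[ValOEt][IBU],skin,43.23
[ValOEt][IBU],strat-m,77.66
[ValOiPr][IBU],skin,43.71
[ValOiPr][IBU],strat-m,177.23
[ValOPr][IBU],skin,56.56
[ValOPr][IBU],strat-m,205.81
[ValOBu][IBU],skin,49.73
[ValOBu][IBU],strat-m,153.29
[ValOAm][IBU],skin,55.10
[ValOAm][IBU],strat-m,172.48
[ValOHex][IBU],skin,43.65
[ValOHex][IBU],strat-m,50.23
[ValOHept][IBU],skin,32.47
[ValOHept][IBU],strat-m,93.98
[ValOOct][IBU],skin,23.80
[ValOOct][IBU],strat-m,31.96
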