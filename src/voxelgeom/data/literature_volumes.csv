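structure,author,year,method,volume_mm3
STN,Fussenich,1967,Microscopy,64.0
STN,Hardman et al.,2002,Microscopy,120.0
STN,Levesque & Parent,2005,Microscopy,175.0
STN,"Lange, Thorner, Hopf, & Schroder",1976,Microscopy,141.0
STN,Massey et al.,2012,MRI 9.4T,106.0
STN,"Nowinski, Belov, Pollak, & Benabid",2005,Atlas reconstruction,174.0
STN,Plantinga et al.,2016,MRI 7.0T,100.5
STN,Bonin & Shariff,1951,Microscopy,157.0
STN,Weiss et al.,2015,MRI 7.0T,109.0
STN,Yelnik & Percheron,1979,Microscopy,180.0
STN,Zwirner et al.,2017,MRI 3.0T,99.0
STN,Zwirner et al.,2017,Microscopy,131.0
GPi,Lange et al.,1976,Microscopy,494.0
GPi,"Mai, Majtanik, & Paxinos",2015,Microscopy,263.5
GPi,Plantinga et al.,2016,MRI 7.0T,271.8
GPi,Yelnik & Percheron,1979,Microscopy,478.0
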