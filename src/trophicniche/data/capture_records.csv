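species,individual,sex,body_mass_kg,body_length_cm,capture_date,end_tracking,tracking_days,whisker_length_mm,n_whisker_segments
harbour,S01,M,86,141,2008-10-20,2009-01-13,85,65,7
harbour,S02,M,82,151,2008-10-20,2009-05-04,196,103,10
harbour,S03,M,85,139,2008-10-20,2009-04-03,165,88,10
harbour,S04,M,55,130,2008-10-21,2009-02-19,121,109,11
harbour,S05,M,89,140,2008-10-21,2009-01-28,99,102,11
harbour,S06,F,77,143,2008-10-21,2009-01-03,74,62,7
harbour,S07,M,98,144,2008-10-21,2009-05-05,196,116,13
harbour,S08,M,83,138,2008-10-21,2009-05-05,196,90,10
grey,G01,M,98,148,2012-05-29,2012-10-30,154,82,9
grey,G02,M,150,188,2012-05-30,2012-10-20,143,72,8
grey,G03,M,112,162,2012-05-30,2012-12-16,200,114,12
grey,G04,M,146,173,2012-05-30,2012-11-30,184,72,8
grey,G05,M,86,149,2012-05-30,2012-11-03,157,110,12
grey,G07,M,180,202,2012-05-31,2012-09-03,95,52,6
grey,G08,M,139,183,2012-05-31,2013-01-09,223,100,11
grey,G09,M,61,140,2012-06-01,,,132,14
grey,G10,M,70,149,2012-09-10,2012-10-04,24,102,11
grey,G12,M,200,205,2012-09-13,2013-01-02,111,110,12
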