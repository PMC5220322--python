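source,target,sex,nuclide,value_mGy_per_MBqh,provenance
kidneys,pancreas,male,In-111,5.298588490770901e-03,derived: 24.4 mGy / (tau 30.7 MBq.h/MBq x 150 MBq); healthy adult male kidney-to-pancreas term
pancreas,pancreas,male,In-111,3.661691542288557e-01,derived: 3.68 mGy / (tau 6.70E-2 x 150 MBq); healthy adult male pancreas self term
kidneys,pancreas,male,Ga-68,1.226666666666667e-02,derived: 0.46 mGy / (tau 0.50 x 75 MBq); healthy adult male kidney-to-pancreas term
pancreas,pancreas,male,Ga-68,4.848484848484849e+00,derived: 0.40 mGy / (tau 1.10E-3 x 75 MBq); healthy adult male pancreas self term
kidneys,pancreas,female,In-111,6.384364820846906e-03,derived: 29.4 mGy / (tau 30.7 x 150 MBq); healthy adult female kidney-to-pancreas term
pancreas,pancreas,female,In-111,4.016877637130802e-01,derived: 4.76 mGy / (tau 7.90E-2 x 150 MBq); healthy adult female pancreas self term
kidneys,pancreas,female,Ga-68,1.413333333333333e-02,derived: 0.53 mGy / (tau 0.50 x 75 MBq); healthy adult female kidney-to-pancreas term
pancreas,pancreas,female,Ga-68,5.333333333333333e+00,derived: 0.52 mGy / (tau 1.30E-3 x 75 MBq); healthy adult female pancreas self term
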