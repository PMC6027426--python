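<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level2" level="2" version="1">
  <model id="l2_toy" name="legacy toy">
    <listOfCompartments>
      <compartment id="c" name="cytosol"/>
    </listOfCompartments>
    <listOfSpecies>
      <species id="A" name="A" compartment="c" boundaryCondition="false"/>
      <species id="B" name="B" compartment="c" boundaryCondition="false"/>
    </listOfSpecies>
    <listOfReactions>
      <reaction id="EX_A" reversible="true">
        <listOfReactants>
          <speciesReference species="A" stoichiometry="1"/>
        </listOfReactants>
        <kineticLaw>
          <math xmlns="http://www.w3.org/1998/Math/MathML"><ci>FLUX_VALUE</ci></math>
          <listOfParameters>
            <parameter id="LOWER_BOUND" value="-10" units="dimensionless"/>
            <parameter id="UPPER_BOUND" value="0" units="dimensionless"/>
            <parameter id="FLUX_VALUE" value="0" units="dimensionless"/>
            <parameter id="OBJECTIVE_COEFFICIENT" value="0" units="dimensionless"/>
          </listOfParameters>
        </kineticLaw>
      </reaction>
      <reaction id="CONV" reversible="false">
        <listOfReactants>
          <speciesReference species="A" stoichiometry="1"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="B" stoichiometry="0.5"/>
        </listOfProducts>
        <notes><body xmlns="http://www.w3.org/1999/xhtml"><p>GENE_ASSOCIATION: gC1 and gC2</p></body></notes>
        <kineticLaw>
          <math xmlns="http://www.w3.org/1998/Math/MathML"><ci>FLUX_VALUE</ci></math>
          <listOfParameters>
            <parameter id="LOWER_BOUND" value="0" units="dimensionless"/>
            <parameter id="UPPER_BOUND" value="999999" units="dimensionless"/>
            <parameter id="FLUX_VALUE" value="0" units="dimensionless"/>
            <parameter id="OBJECTIVE_COEFFICIENT" value="0" units="dimensionless"/>
          </listOfParameters>
        </kineticLaw>
      </reaction>
      <reaction id="BIO" reversible="false">
        <listOfReactants>
          <speciesReference species="B" stoichiometry="1"/>
        </listOfReactants>
        <kineticLaw>
          <math xmlns="http://www.w3.org/1998/Math/MathML"><ci>FLUX_VALUE</ci></math>
          <listOfParameters>
            <parameter id="LOWER_BOUND" value="0" units="dimensionless"/>
            <parameter id="UPPER_BOUND" value="999999" units="dimensionless"/>
            <parameter id="FLUX_VALUE" value="0" units="dimensionless"/>
            <parameter id="OBJECTIVE_COEFFICIENT" value="1" units="dimensionless"/>
          </listOfParameters>
        </kineticLaw>
      </reaction>
    </listOfReactions>
  </model>
</sbml>
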